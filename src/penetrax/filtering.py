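"""Rare-variant QC: genotype-level GQ/DP masking, synonymous removal, and
per-ancestry frequency filtering.

Genotype-level masking runs first (a call with GQ <= 90 or DP <= 10 is set to
missing; strict ">" retention).  Variant-level filters follow: synonymous
consequences are dropped, then any variant whose allele frequency exceeds its
gene's ceiling in ANY (source, ancestry) cell is dropped.  A missing frequency
cell never fails the filter.  The cohort's own post-masking allele frequency
is recomputed and participates as one of the sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genes import DEFAULT_MAF_THRESHOLDS, GENE_CHROMOSOME, GENE_SETS

__all__ = [
    "RareGenotypes",
    "FilterReport",
    "mask_low_quality_genotypes",
    "compute_cohort_af",
    "apply_frequency_filter",
    "drop_synonymous",
    "filter_variants",
]

GQ_MIN = 90  # retained only if GQ > 90
DP_MIN = 10  # retained only if DP > 10

MISSING = np.int8(-1)


@dataclass
class RareGenotypes:
    """Rare-variant genotype matrix with per-call quality metrics.

    ``gt`` is (n_samples, n_variants) int8 with entries 0/1/2 alternate-allele
    counts and -1 for missing.  Male X-chromosome calls are haploid encoded as
    homozygous (0 or 2) and contribute one allele to frequency denominators.
    """

    variants: pd.DataFrame  # variant_id, gene, chrom, pos, ref, alt
    samples: np.ndarray
    gt: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    sex: np.ndarray | None = None  # 'M'/'F' per sample, needed for X

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.variants)):
            raise ValueError("gt shape must be (n_samples, n_variants)")

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def subset_variants(self, variant_ids) -> "RareGenotypes":
        keep = self.variants["variant_id"].isin(set(variant_ids)).to_numpy()
        return replace(
            self,
            variants=self.variants.loc[keep].reset_index(drop=True),
            gt=self.gt[:, keep],
            gq=None if self.gq is None else self.gq[:, keep],
            dp=None if self.dp is None else self.dp[:, keep],
        )

    def allele_counts(self):
        """(alt allele count, called allele number) per variant, honoring
        male X hemizygosity."""
        gt = self.gt
        called = gt >= 0
        is_x = (self.variants["chrom"].to_numpy() == "X")[None, :]
        if self.sex is not None:
            male = np.array([str(s).upper().startswith("M") for s in self.sex])[:, None]
        else:
            male = np.zeros((len(self.samples), 1), dtype=bool)
        hemi = is_x & male
        ploidy = np.where(hemi, 1, 2)
        alt = np.where(hemi, (gt > 0).astype(np.int32), np.maximum(gt, 0).astype(np.int32))
        ac = (alt * called).sum(axis=0)
        an = (ploidy * called).sum(axis=0)
        return ac, an


@dataclass
class FilterReport:
    """First-removing-filter attribution; counts partition the input set."""

    n_input: int = 0
    n_removed_gq_dp: int = 0
    n_removed_synonymous: int = 0
    n_removed_maf: int = 0
    n_surviving: int = 0
    n_genotypes_masked: int = 0
    removed_by_filter: dict = field(default_factory=dict)

    def check_partition(self):
        total = (
            self.n_removed_gq_dp
            + self.n_removed_synonymous
            + self.n_removed_maf
            + self.n_surviving
        )
        if total != self.n_input:
            raise AssertionError("filter report counts do not partition the input")
        return True

    def to_dict(self) -> dict:
        return {
            "input": self.n_input,
            "removed_gq_dp": self.n_removed_gq_dp,
            "removed_synonymous": self.n_removed_synonymous,
            "removed_maf": self.n_removed_maf,
            "surviving": self.n_surviving,
            "genotypes_masked": self.n_genotypes_masked,
        }


def mask_low_quality_genotypes(
    rare: RareGenotypes, gq_min: int = GQ_MIN, dp_min: int = DP_MIN
) -> tuple[RareGenotypes, int, np.ndarray]:
    """Set calls with GQ <= gq_min or DP <= dp_min to missing.

    Returns (masked genotypes, n calls masked, per-variant flag of variants
    left with no non-missing alternate call — those are removed downstream).
    """
    if rare.gq is None or rare.dp is None:
        raise ValueError(
            "GQ/DP fields are required for genotype masking; "
            f"missing on genotype matrix with variants {rare.variant_ids[:3]}..."
        )
    bad = (rare.gq <= gq_min) | (rare.dp <= dp_min)
    bad &= rare.gt >= 0
    gt = rare.gt.copy()
    gt[bad] = MISSING
    masked = replace(rare, gt=gt)
    no_alt = ~((gt > 0).any(axis=0))
    return masked, int(bad.sum()), no_alt


def compute_cohort_af(
    rare: RareGenotypes,
    ancestry_labels: np.ndarray | None = None,
    source: str = "observed",
) -> pd.DataFrame:
    """Post-masking alternate-allele frequency per variant, overall and per
    ancestry group, as annotation-table style ``af_<source>_<ancestry>`` columns."""
    out = {"variant_id": rare.variant_ids}
    ac, an = rare.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        out[f"af_{source}_all"] = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    if ancestry_labels is not None:
        ancestry_labels = np.asarray(ancestry_labels)
        for anc in pd.unique(ancestry_labels):
            sub = replace(
                rare,
                samples=rare.samples[ancestry_labels == anc],
                gt=rare.gt[ancestry_labels == anc],
                gq=None,
                dp=None,
                sex=None if rare.sex is None else rare.sex[ancestry_labels == anc],
            )
            ac_g, an_g = sub.allele_counts()
            with np.errstate(invalid="ignore", divide="ignore"):
                out[f"af_{source}_{str(anc).lower()}"] = np.where(
                    an_g > 0, ac_g / np.maximum(an_g, 1), np.nan
                )
    return pd.DataFrame(out)


def _af_columns(annotation: pd.DataFrame) -> list[str]:
    return [c for c in annotation.columns if c.startswith("af_")]


def apply_frequency_filter(
    annotation: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    gene_set: str | None = None,
) -> pd.Series:
    """Boolean survivor mask: a variant survives only if its allele frequency
    is <= its gene's ceiling in EVERY non-missing (source, ancestry) cell.

    ``thresholds`` maps gene -> max AF (defaults: 1e-5 ADPKD, 1e-3 COL4A).
    ``gene_set`` optionally restricts to 'adpkd' or 'col4a' genes (variants
    outside the set are marked non-surviving).
    """
    thr = dict(DEFAULT_MAF_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    genes = annotation["gene"]
    unknown = set(genes.unique()) - set(thr)
    if unknown:
        raise ValueError(f"unknown gene(s) in annotation: {sorted(unknown)}")
    max_af = genes.map(thr).to_numpy(dtype=float)
    af = annotation[_af_columns(annotation)].to_numpy(dtype=float)
    exceeds = np.nanmax(np.where(np.isnan(af), -np.inf, af), axis=1) > max_af
    survives = ~exceeds
    if gene_set is not None:
        survives &= genes.isin(GENE_SETS[gene_set]).to_numpy()
    return pd.Series(survives, index=annotation.index, name="passes_af")


def drop_synonymous(annotation: pd.DataFrame) -> pd.Series:
    """Survivor mask removing synonymous consequences."""
    return pd.Series(
        annotation["consequence"].to_numpy() != "synonymous",
        index=annotation.index,
        name="passes_consequence",
    )


def filter_variants(
    rare: RareGenotypes,
    annotation: pd.DataFrame,
    ancestry_labels: np.ndarray | None = None,
    thresholds: dict[str, float] | None = None,
    gene_set: str | None = None,
    gq_min: int = GQ_MIN,
    dp_min: int = DP_MIN,
) -> tuple[RareGenotypes, pd.DataFrame, FilterReport]:
    """Full QC cascade: mask genotypes, recompute cohort AF, drop synonymous,
    apply the frequency filter.  Returns (masked+subset genotypes, surviving
    annotation with observed AF columns appended, FilterReport)."""
    annotation = annotation.reset_index(drop=True)
    order = {v: i for i, v in enumerate(rare.variant_ids)}
    missing_ids = [v for v in annotation["variant_id"] if v not in order]
    if missing_ids:
        warnings.warn(f"{len(missing_ids)} annotated variants absent from genotypes")

    masked, n_masked, no_alt = mask_low_quality_genotypes(rare, gq_min, dp_min)
    no_alt_ids = set(masked.variant_ids[no_alt])

    observed = compute_cohort_af(masked, ancestry_labels, source="observed")
    annot = annotation.merge(observed, on="variant_id", how="left")

    report = FilterReport(n_input=len(annot), n_genotypes_masked=n_masked)
    removed_gq = annot["variant_id"].isin(no_alt_ids).to_numpy()
    syn = ~drop_synonymous(annot).to_numpy()
    maf = ~apply_frequency_filter(annot, thresholds, gene_set).to_numpy()

    # first-filter attribution: masking, then synonymous, then frequency
    attr = np.full(len(annot), "surviving", dtype=object)
    attr[maf] = "maf"
    attr[syn] = "synonymous"
    attr[removed_gq] = "gq_dp"
    report.n_removed_gq_dp = int((attr == "gq_dp").sum())
    report.n_removed_synonymous = int((attr == "synonymous").sum())
    report.n_removed_maf = int((attr == "maf").sum())
    report.n_surviving = int((attr == "surviving").sum())
    report.removed_by_filter = {
        str(v): str(a) for v, a in zip(annot["variant_id"], attr) if a != "surviving"
    }
    report.check_partition()

    surviving = annot.loc[attr == "surviving"].reset_index(drop=True)
    out_gt = masked.subset_variants(surviving["variant_id"])
    return out_gt, surviving, report
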