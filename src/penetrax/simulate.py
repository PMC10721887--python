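"""Synthetic two-cohort biobank generator with planted effects.

Generates everything the penetrance pipeline consumes: rare-variant
genotypes with per-call GQ/DP, an annotation table populating every
qualifying-variant rule branch (pLOF, asserted P/LP with submitter counts,
single-submitter and conflict exclusions, benign vetoes, deleterious and
non-deleterious missense, synonymous, frequency-filtered and low-quality
decoys), LD-structured common-variant dosages with a score weights table, a
labeled reference panel emulating a 1000 Genomes-style resource, phenotypes
(creatinine back-computed from a target eGFR via the 2009 CKD-EPI inverse,
RRT and billing codes, diabetes, batch), an ICD->phecode map, and a truth
record sufficient to score every downstream decision.

Disease status is drawn on the logistic scale:

    logit P(CKD) = b0 + bc*carrier + bg*GPS_std + bi*carrier*GPS_std
                   + ba*APOL1 + b_age*(age-50)/10 + b_male*male + b_dm*diabetes

so planted log odds ratios are directly recoverable by the analysis modules.
The two cohorts differ in ancestry mix (~94% vs ~43% European) and age range
(40-69 vs 18-89), mirroring the demographic contrast between a UK-style and
a US-style biobank.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .filtering import RareGenotypes
from .genes import (ADPKD_GENES, ANCESTRIES, COL4A_GENES,
                    DEFAULT_MAF_THRESHOLDS, GENE_CHROMOSOME, GENE_SETS)
from .phenotyping import invert_egfr_2009

__all__ = ["SimConfig", "CohortSpec", "SimulatedCohort", "SimulatedStudy",
           "simulate_cohort", "write_reference_panel", "make_phecode_map"]

# one template cycle of planted variant classes; repeated to n_rare_variants
# per gene.  Classes marked qv_* enter the corresponding truth QV sets.
CLASS_TEMPLATE = (
    "plof", "plof", "plof",
    "clinvar_P", "clinvar_P",
    "clinvar_LP",
    "del_missense", "del_missense",
    "plof_benign",        # pLOF vetoed by a Varsome LB assertion
    "clinvar_P_single",   # P but a single submitter: excluded
    "clinvar_P_conflict", # P with assertion conflict: excluded
    "vus_missense",       # low REVEL missense, ClinVar VUS
    "synonymous",
    "common_benign",      # B, frequency above the gene's ceiling
    "low_quality",        # pLOF whose alternate calls all fail GQ/DP
    "missense_4of5",      # REVEL high but only 4/5 predictors damaging
)

CLASS_QV = {
    "plof": ("M1", "M2", "M3"),
    "clinvar_P": ("M1", "M2"),
    "clinvar_LP": ("M2",),
    "del_missense": ("M3",),
    # annotation-qualifying, but its alternate calls all fail GQ/DP so it
    # never survives genotype masking (truth carrier flags intersect with
    # the surviving-variant mask)
    "low_quality": ("M1", "M2", "M3"),
}


@dataclass
class CohortSpec:
    name: str
    n_participants: int = 200_000
    ancestry_mixture: dict = field(
        default_factory=lambda: {"EUR": 0.94, "AFR": 0.02, "EAS": 0.015,
                                 "SAS": 0.015, "AMR": 0.01}
    )
    age_range: tuple = (40, 69)
    female_fraction: float = 0.54
    n_batches: int = 2


def _default_cohorts():
    return [
        CohortSpec("cohort1"),
        CohortSpec(
            "cohort2",
            n_participants=75_000,
            ancestry_mixture={"EUR": 0.43, "AFR": 0.21, "EAS": 0.04,
                              "SAS": 0.15, "AMR": 0.17},
            age_range=(18, 89),
            female_fraction=0.60,
        ),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults plant a 17-fold carrier odds ratio for the analyzed (ADPKD)
    gene set at a carrier frequency of 6e-4 (about 120 carriers in the
    200,000-participant cohort), a 1.7-fold per-SD polygenic score effect,
    a null carrier-by-score interaction, an APOL1 recessive effect, a 3%
    baseline case rate, and the frequency-filter-compatible rare-variant
    architecture described in the class template.
    """

    cohorts: list = field(default_factory=_default_cohorts)
    n_rare_variants_per_gene: int = 112
    carrier_frequency: dict = field(
        default_factory=lambda: {"adpkd": 6e-4, "col4a": 2e-3}
    )
    maf_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_MAF_THRESHOLDS)
    )
    analysis_gene_set: str = "adpkd"
    n_common_variants: int = 400
    n_score_variants: int = 200
    ld_block_size: int = 20
    ld_rho: float = 0.5
    fst: float = 0.1
    planted_carrier_logOR: float = float(np.log(17.0))
    planted_gps_logOR_per_SD: float = float(np.log(1.7))
    planted_interaction_logOR: float = 0.0
    baseline_case_rate: float = 0.03
    apol1_risk_genotype_freq: dict = field(
        default_factory=lambda: {"EUR": 0.001, "AFR": 0.12, "EAS": 0.001,
                                 "SAS": 0.001, "AMR": 0.02}
    )
    apol1_logOR: float = float(np.log(1.8))
    age_logOR_per_decade: float = 0.3
    male_logOR: float = 0.2
    diabetes_logOR: float = 0.7
    diabetes_prevalence: float = 0.10
    missing_creatinine_rate: float = 0.02
    exclusion_tranche_rate: float = 0.15
    rrt_rate_given_case: float = 0.08
    control_ckd_code_rate: float = 0.003
    seed: int = 1

    def validate(self):
        for spec in self.cohorts:
            total = sum(spec.ancestry_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{spec.name}: ancestry proportions sum to {total}")
            if spec.n_participants <= 0:
                raise ValueError("n_participants must be positive")
        probs = [self.baseline_case_rate, self.missing_creatinine_rate,
                 self.exclusion_tranche_rate, self.rrt_rate_given_case,
                 self.diabetes_prevalence, *self.carrier_frequency.values(),
                 *self.apol1_risk_genotype_freq.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_rare_variants_per_gene <= 0 or self.n_common_variants <= 0:
            raise ValueError("variant counts must be positive")
        for gene_set, freq in self.carrier_frequency.items():
            for spec in self.cohorts:
                if spec.n_participants * freq < 1.0:
                    raise ValueError(
                        f"expected carrier count < 1 for gene set {gene_set!r} in "
                        f"{spec.name} (underpowered stratum): n={spec.n_participants}, "
                        f"carrier_frequency={freq}"
                    )
        return self


# ----------------------------------------------------------------- variants

def _variant_table(config: SimConfig, rng) -> pd.DataFrame:
    """Planted rare-variant truth: gene, class, QV membership, database AFs."""
    rows = []
    for gene in list(ADPKD_GENES) + list(COL4A_GENES):
        chrom = GENE_CHROMOSOME[gene]
        classes = [CLASS_TEMPLATE[i % len(CLASS_TEMPLATE)]
                   for i in range(config.n_rare_variants_per_gene)]
        for i, cls in enumerate(classes):
            rows.append({
                "variant_id": f"{gene}_rv{i:03d}",
                "gene": gene,
                "chrom": chrom,
                "pos": 1_000_000 + 100 * i,
                "ref": "A",
                "alt": "T",
                "true_class": cls,
                "qv_m1": "M1" in CLASS_QV.get(cls, ()),
                "qv_m2": "M2" in CLASS_QV.get(cls, ()),
                "qv_m3": "M3" in CLASS_QV.get(cls, ()),
            })
    var = pd.DataFrame(rows)

    thr = var["gene"].map(config.maf_thresholds).to_numpy(dtype=float)
    for source in ("cohort1", "cohort2", "gnomad"):
        for anc in ANCESTRIES:
            af = thr * rng.uniform(0.2, 0.8, size=len(var))
            var[f"af_{source}_{anc.lower()}"] = af
    # the frequency-filtered decoy exceeds its ceiling in exactly one
    # ancestral group of one source ("in any ancestral group" semantics)
    over = var["true_class"] == "common_benign"
    var.loc[over, "af_gnomad_afr"] = 5.0 * thr[over.to_numpy()]
    return var


def _annotation_from_truth(var: pd.DataFrame, rng) -> pd.DataFrame:
    """Annotation table consistent with each variant's planted class."""
    n = len(var)
    annot = var[["variant_id", "gene"]].copy()
    cls = var["true_class"].to_numpy()

    consequence = np.full(n, "missense", dtype=object)
    plof_pool = np.array(["stop_gained", "frameshift", "stop_lost", "start_lost",
                          "splice_acceptor", "splice_donor"], dtype=object)
    for c in ("plof", "plof_benign", "low_quality"):
        sel = cls == c
        consequence[sel] = plof_pool[rng.integers(0, len(plof_pool), size=sel.sum())]
    consequence[cls == "synonymous"] = "synonymous"
    annot["consequence"] = consequence

    revel = rng.uniform(0.0, 0.4, size=n)
    revel[np.isin(cls, ("del_missense", "missense_4of5"))] = rng.uniform(
        0.75, 0.99, size=int(np.isin(cls, ("del_missense", "missense_4of5")).sum()))
    revel[~np.isin(consequence, ("missense",))] = np.nan
    annot["revel"] = np.round(revel, 3)

    verdicts = np.full((n, 5), "tolerated", dtype=object)
    verdicts[np.isin(consequence, ("missense",)) == False] = "missing"
    dm = cls == "del_missense"
    verdicts[dm] = "damaging"
    four = cls == "missense_4of5"
    verdicts[four] = "damaging"
    verdicts[four, 4] = "tolerated"
    for j, col in enumerate(("sift", "polyphen2_hdiv", "polyphen2_hvar",
                             "lrt", "mutation_taster")):
        annot[col] = verdicts[:, j]

    clinvar = np.full(n, "none", dtype=object)
    n_sub = np.zeros(n, dtype=int)
    conflict = np.zeros(n, dtype=bool)
    varsome = np.full(n, "none", dtype=object)

    clinvar[np.isin(cls, ("clinvar_P", "clinvar_P_single", "clinvar_P_conflict"))] = "P"
    clinvar[cls == "clinvar_LP"] = "LP"
    clinvar[cls == "vus_missense"] = "VUS"
    clinvar[cls == "common_benign"] = "B"
    n_sub[np.isin(cls, ("clinvar_P", "clinvar_LP", "clinvar_P_conflict"))] = rng.integers(
        2, 6, size=int(np.isin(cls, ("clinvar_P", "clinvar_LP", "clinvar_P_conflict")).sum()))
    n_sub[cls == "clinvar_P_single"] = 1
    n_sub[cls == "vus_missense"] = 1
    n_sub[cls == "common_benign"] = 3
    conflict[cls == "clinvar_P_conflict"] = True
    varsome[cls == "plof_benign"] = "LB"
    varsome[cls == "clinvar_P"] = "VUS"  # a Varsome VUS never vetoes

    annot["clinvar_assertion"] = clinvar
    annot["clinvar_n_submitters"] = n_sub
    annot["clinvar_conflict_flag"] = conflict
    annot["varsome_assertion"] = varsome
    for c in var.columns:
        if c.startswith("af_"):
            annot[c] = var[c].to_numpy()
    return annot


# ----------------------------------------------------------------- panel

_PANEL_SIZES = {"EUR": 503, "AFR": 661, "EAS": 504, "SAS": 489, "AMR": 347}


def _common_freqs(config: SimConfig, rng) -> np.ndarray:
    """Per-ancestry allele frequencies (Balding-Nichols differentiation)."""
    m = config.n_common_variants
    p_anc = rng.uniform(0.1, 0.9, size=m)
    f = config.fst
    a, b = p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f
    freqs = np.vstack([np.clip(rng.beta(a, b), 0.01, 0.99) for _ in ANCESTRIES])
    return freqs  # (5 ancestries, m variants)


def write_reference_panel(
    config: SimConfig,
    rng=None,
    freqs: np.ndarray | None = None,
    groups: list[str] | None = None,
):
    """Labeled reference genotype panel (2504 samples, 1000 Genomes-style
    group sizes) at the study's common variants.

    Returns (dosages int8, labels, sample ids, variant ids).  Requires at
    least two ancestry groups and at least 50 panel samples per group.
    """
    rng = np.random.default_rng(config.seed + 7) if rng is None else rng
    groups = list(groups) if groups is not None else list(ANCESTRIES)
    if len(groups) < 2:
        raise ValueError("reference panel needs at least 2 ancestry groups")
    for g in groups:
        if _PANEL_SIZES.get(g, 0) < 50:
            raise ValueError(f"fewer than 50 panel samples for group {g}")
    if freqs is None:
        freqs = _common_freqs(config, rng)
    anc_idx = {a: i for i, a in enumerate(ANCESTRIES)}
    dosage_blocks, labels = [], []
    for g in groups:
        n_g = _PANEL_SIZES[g]
        p = freqs[anc_idx[g]]
        dosage_blocks.append(rng.binomial(2, p, size=(n_g, len(p))).astype(np.int8))
        labels.extend([g] * n_g)
    dosages = np.vstack(dosage_blocks)
    sample_ids = np.array([f"ref{i:05d}" for i in range(len(labels))])
    variant_ids = np.array([f"cv{j:05d}" for j in range(dosages.shape[1])])
    return dosages, np.array(labels), sample_ids, variant_ids


# ----------------------------------------------------------------- phecodes

def make_phecode_map() -> pd.DataFrame:
    """Synthetic ICD-9 -> phecode map with exclusion ranges and system groups."""
    rows = [
        # phecode, icd9, exclusion_range, system_group, label
        (585.3, "585.3", "580-599.99", "genitourinary", "Chronic kidney disease"),
        (585.3, "585.9", "580-599.99", "genitourinary", "Chronic kidney disease"),
        (599.7, "599.7", "580-599.99", "genitourinary", "Hematuria"),
        (580.1, "580.9", "580-599.99", "genitourinary", "Nephritis"),
        (753.1, "753.1", "753-753.99", "congenital", "Cystic kidney disease"),
        (401.1, "401.1", "401-405.99", "circulatory", "Hypertension"),
        (401.1, "401.9", "401-405.99", "circulatory", "Hypertension"),
        (250.2, "250.00", "249-250.99", "endocrine", "Type 2 diabetes"),
        (300.1, "300.00", "295-306.99", "mental", "Anxiety disorder"),
        (495.0, "493.9", "490-496.99", "respiratory", "Asthma"),
        (715.1, "715.9", "710-716.99", "musculoskeletal", "Osteoarthritis"),
        (365.0, "365.9", "360-379.99", "sense organs", "Glaucoma"),
    ]
    return pd.DataFrame(rows, columns=["phecode", "icd9", "exclusion_range",
                                       "system_group", "label"])


# ----------------------------------------------------------------- cohorts

@dataclass
class SimulatedCohort:
    name: str
    phenotypes: pd.DataFrame
    rare: RareGenotypes
    annotation: pd.DataFrame
    dosages: np.ndarray          # (n, m) int8
    dosage_variant_ids: np.ndarray
    truth: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimConfig
    cohorts: dict
    weights: pd.DataFrame
    panel_dosages: np.ndarray
    panel_labels: np.ndarray
    panel_samples: np.ndarray
    panel_variant_ids: np.ndarray
    phecode_map: pd.DataFrame
    truth_variants: pd.DataFrame

    def write(self, outdir):
        """Emit the standard-format files (VCF, TSV, CSV, YAML) to a directory."""
        from . import _io
        _io.write_study(self, outdir)


def _ar1_dosages(n, freqs_row_idx, freqs, block, rho, rng, chunk=20_000):
    """Common-variant dosages with AR(1) latent LD within blocks, marginally
    Binomial(2, p_ancestry) per variant."""
    m = freqs.shape[1]
    thresholds = ndtri(freqs)  # (5, m)
    out = np.empty((n, m), dtype=np.int8)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        thr = thresholds[freqs_row_idx[start:stop]]  # (c, m)
        dose = np.zeros((stop - start, m), dtype=np.int8)
        for _hap in range(2):
            z = rng.standard_normal((stop - start, m))
            for j in range(1, m):
                if j % block:
                    z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
            dose += (z < thr).astype(np.int8)
        out[start:stop] = dose
    return out


def _sample_rare_genotypes(spec, var, config, truth, rng):
    """Rare-variant genotype/GQ/DP matrices with planted carriers.

    Liability carriers of the analyzed gene set are spread round-robin over
    that set's M1 truth QVs (so ultra-rare frequency ceilings hold); every
    other variant receives independent het carriers at its planted frequency.
    Recessive genotypes (compound het, an in-cis pair, a homozygote, male
    hemizygotes) are planted explicitly in the COL4A genes.
    """
    n = spec.n_participants
    m = len(var)
    gt = np.zeros((n, m), dtype=np.int8)
    gq = rng.integers(91, 100, size=(n, m), dtype=np.int8)
    dp = rng.integers(11, 61, size=(n, m), dtype=np.int8)
    # sprinkle low-quality reference calls to exercise masking (column-wise
    # to bound memory at large n)
    for j in range(m):
        gq[rng.random(n) < 0.02, j] = 60

    male = truth["sex"].to_numpy() == "M"
    vclass = var["true_class"].to_numpy()
    vgene = var["gene"].to_numpy()
    vchrom = var["chrom"].to_numpy()
    max_alleles = {  # max planted alt alleles under each gene's AF ceiling
        g: int(np.floor(config.maf_thresholds[g] * 2 * n)) for g in GENE_CHROMOSOME
    }

    def _force_good_call(rows, col):
        rows = np.atleast_1d(rows)
        gq[rows, col] = rng.integers(95, 100, size=len(rows), dtype=np.int8)
        dp[rows, col] = rng.integers(20, 61, size=len(rows), dtype=np.int8)

    carrier_cols: dict[str, np.ndarray] = {}
    for gene_set, genes in GENE_SETS.items():
        freq = config.carrier_frequency[gene_set]
        carriers = np.flatnonzero(rng.random(n) < freq)
        pool = np.flatnonzero(np.isin(vgene, genes) & var["qv_m1"].to_numpy()
                              & (vclass != "low_quality"))
        cap = {j: max(1, max_alleles[vgene[j]] - 1) for j in pool}
        assigned = np.full(len(carriers), -1, dtype=int)
        counts = {j: 0 for j in pool}
        k = 0
        for idx in range(len(carriers)):
            for _ in range(len(pool)):
                j = pool[k % len(pool)]
                k += 1
                if counts[j] < cap[j]:
                    assigned[idx] = j
                    counts[j] += 1
                    break
        for pid, j in zip(carriers, assigned):
            if j < 0:
                continue
            if vchrom[j] == "X" and male[pid]:
                gt[pid, j] = 2  # hemizygous, haploid-as-homozygous
            else:
                gt[pid, j] = 1
            _force_good_call(pid, j)
        # liability carriers are those actually granted a genotype: at small n
        # the frequency ceiling caps per-variant carriers and the overflow is
        # not planted (the generator warns via the validate() precondition)
        carrier_cols[gene_set] = carriers[assigned >= 0]

    # independent het carriers for every non-liability variant at its planted AF
    for j in range(m):
        if vclass[j] in ("plof", "clinvar_P") and var["qv_m1"].iloc[j]:
            continue  # liability pool handled above
        thr_j = config.maf_thresholds[vgene[j]]
        maf = 2.0 * thr_j if vclass[j] == "common_benign" else 0.2 * thr_j
        k = rng.binomial(n, 2 * maf)
        if k == 0:
            continue
        rows = rng.choice(n, size=min(k, n), replace=False)
        if vchrom[j] == "X":
            gt[rows, j] = np.where(male[rows], 2, 1).astype(np.int8)
        else:
            gt[rows, j] = 1
        if vclass[j] == "low_quality":
            gq[rows, j] = 50
            dp[rows, j] = 5
        else:
            _force_good_call(rows, j)

    # --- planted recessive genotypes in the COL4A genes ---
    def _pick(gene, cls, nth=0):
        cand = np.flatnonzero((vgene == gene) & (vclass == cls))
        return cand[nth % len(cand)]

    spare = rng.choice(n, size=8, replace=False)
    # compound heterozygote: two distinct het QVs in COL4A3
    for t, pid in enumerate(spare[:2]):
        for nth in (2 * t, 2 * t + 1):
            j = _pick("COL4A3", "plof", nth)
            gt[pid, j] = 1
            _force_good_call(pid, j)
    # an in-cis pair (unphased data cannot distinguish it; truth flags it)
    cis_pid = spare[2]
    for nth in (4, 5):
        j = _pick("COL4A3", "plof", nth)
        gt[cis_pid, j] = 1
        _force_good_call(cis_pid, j)
    # homozygous alternate QV in COL4A4 (pLOF: visible under every model)
    hom_pid = spare[3]
    j = _pick("COL4A4", "plof", 0)
    gt[hom_pid, j] = 2
    _force_good_call(hom_pid, j)
    # male COL4A5 hemizygotes
    males = np.flatnonzero(male)
    hemi_pids = males[rng.integers(0, len(males), size=2)]
    for t, pid in enumerate(hemi_pids):
        j = _pick("COL4A5", "plof", t)
        gt[pid, j] = 2
        _force_good_call(pid, j)

    planted = {
        "comp_het": [int(x) for x in spare[:2]],
        "in_cis": int(cis_pid),
        "hom": int(hom_pid),
        "hemi": [int(x) for x in hemi_pids],
    }
    return gt, gq, dp, carrier_cols, planted


def simulate_cohort(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate the full synthetic study (all cohorts plus shared resources)."""
    config = (config or SimConfig()).validate()
    rng = np.random.default_rng(config.seed)
    var_rng, annot_rng, panel_rng, weight_rng = rng.spawn(4)

    truth_variants = _variant_table(config, var_rng)
    annotation_master = _annotation_from_truth(truth_variants, annot_rng)
    freqs = _common_freqs(config, panel_rng)
    panel_dos, panel_lab, panel_ids, cv_ids = write_reference_panel(
        config, panel_rng, freqs=freqs)

    weights = pd.DataFrame({
        "variant_id": cv_ids[: config.n_score_variants],
        "effect_allele": "T",
        "weight": weight_rng.normal(0.0, 1.0, size=config.n_score_variants),
    })
    phecode_map = make_phecode_map()

    cohorts = {}
    for spec in config.cohorts:
        crng = np.random.default_rng(
            np.random.SeedSequence([config.seed, zlib.crc32(spec.name.encode())]))
        cohorts[spec.name] = _simulate_one_cohort(
            spec, config, truth_variants, annotation_master, freqs, weights,
            cv_ids, crng)

    return SimulatedStudy(
        config=config, cohorts=cohorts, weights=weights,
        panel_dosages=panel_dos, panel_labels=panel_lab,
        panel_samples=panel_ids, panel_variant_ids=cv_ids,
        phecode_map=phecode_map, truth_variants=truth_variants,
    )


def _simulate_one_cohort(spec, config, var, annotation, freqs, weights,
                         cv_ids, rng) -> SimulatedCohort:
    n = spec.n_participants
    pid = np.array([f"{spec.name}_p{i:06d}" for i in range(n)])

    anc_names = list(spec.ancestry_mixture)
    probs = np.array([spec.ancestry_mixture[a] for a in anc_names])
    ancestry = np.array(anc_names, dtype=object)[
        rng.choice(len(anc_names), size=n, p=probs)]
    anc_row = np.array([ANCESTRIES.index(a) for a in ancestry])

    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n).astype(float)
    diabetes = rng.random(n) < config.diabetes_prevalence
    batch = np.array([f"b{1 + (x % spec.n_batches)}"
                      for x in rng.integers(0, spec.n_batches, size=n)])

    truth = pd.DataFrame({"participant_id": pid, "cohort": spec.name,
                          "ancestry": ancestry, "sex": sex, "age": age})

    # --- genotypes ---
    gt, gq, dp, carrier_cols, planted = _sample_rare_genotypes(
        spec, var, config, truth, rng)
    dosages = _ar1_dosages(n, anc_row, freqs, config.ld_block_size,
                           config.ld_rho, rng)

    # --- true standardized polygenic score (per-ancestry z-score) ---
    w = weights["weight"].to_numpy()
    raw = dosages[:, : config.n_score_variants].astype(np.float64) @ w
    gps_std = np.empty(n)
    for a in np.unique(ancestry):
        sel = ancestry == a
        sd = raw[sel].std()
        if sel.sum() < 2 or sd == 0:  # degenerate tiny group: global fallback
            gps_std[sel] = (raw[sel] - raw.mean()) / max(raw.std(), 1e-12)
        else:
            gps_std[sel] = (raw[sel] - raw[sel].mean()) / sd

    # --- APOL1 ---
    apol1_freq = np.array([config.apol1_risk_genotype_freq[a] for a in ancestry])
    apol1_risk = rng.random(n) < apol1_freq
    g1 = np.zeros(n, dtype=int)
    g2 = np.zeros(n, dtype=int)
    combo = rng.integers(0, 3, size=n)
    g1[apol1_risk & (combo == 0)] = 2
    g2[apol1_risk & (combo == 1)] = 2
    g1[apol1_risk & (combo == 2)] = 1
    g2[apol1_risk & (combo == 2)] = 1
    single = ~apol1_risk & (rng.random(n) < 0.4)
    which = rng.random(n) < 0.5
    g1[single & which] = 1
    g2[single & ~which] = 1

    # --- liability and disease status ---
    analysis_carriers = np.zeros(n, dtype=bool)
    analysis_carriers[carrier_cols[config.analysis_gene_set]] = True
    logit = (
        np.log(config.baseline_case_rate / (1 - config.baseline_case_rate))
        + config.planted_carrier_logOR * analysis_carriers
        + config.planted_gps_logOR_per_SD * gps_std
        + config.planted_interaction_logOR * analysis_carriers * gps_std
        + config.apol1_logOR * apol1_risk
        + config.age_logOR_per_decade * (age - 50.0) / 10.0
        + config.male_logOR * (sex == "M")
        + config.diabetes_logOR * diabetes
    )
    disease = rng.random(n) < expit(logit)

    # --- phenotype realization consistent with status ---
    label = np.where(disease, "case", "control").astype(object)
    noncase = ~disease
    tranche = noncase & (rng.random(n) < config.exclusion_tranche_rate)
    label[tranche] = "excluded"
    rrt = disease & (rng.random(n) < config.rrt_rate_given_case)
    code_excl = (label == "control") & (rng.random(n) < config.control_ckd_code_rate)
    label[code_excl] = "excluded"

    target = np.empty(n)
    target[disease] = rng.uniform(15.0, 58.0, size=int(disease.sum()))
    target[label == "control"] = rng.uniform(92.0, 120.0, size=int((label == "control").sum()))
    target[code_excl] = rng.uniform(92.0, 120.0, size=int(code_excl.sum()))
    target[tranche] = rng.uniform(61.0, 89.0, size=int(tranche.sum()))
    black = ancestry == "AFR"
    creat = np.round(invert_egfr_2009(target, age, sex, black), 3)

    creat_str = creat.astype(str).astype(object)
    missing = rng.random(n) < config.missing_creatinine_rate
    creat_str[missing] = ""
    label[missing & ~rrt] = "excluded"

    # --- ICD-9 code emission ---
    col4a_carrier = np.zeros(n, dtype=bool)
    col4a_carrier[carrier_cols["col4a"]] = True
    adpkd_carrier = np.zeros(n, dtype=bool)
    adpkd_carrier[carrier_cols["adpkd"]] = True

    codes: list[list[str]] = [[] for _ in range(n)]
    def _emit(mask, code, times=2):
        for i in np.flatnonzero(mask):
            codes[i].extend([code] * times)
    _emit(disease & (rng.random(n) < 0.6), "585.3")
    _emit(code_excl, "585.9")
    _emit(col4a_carrier & (rng.random(n) < 0.25), "599.7")
    _emit((~col4a_carrier) & (rng.random(n) < 0.01), "599.7")
    _emit(adpkd_carrier & (rng.random(n) < 0.5), "753.1")
    _emit((~adpkd_carrier) & (rng.random(n) < 0.005), "753.1")
    _emit(rng.random(n) < 0.20, "401.9")
    _emit(rng.random(n) < 0.05, "300.00")
    _emit(rng.random(n) < 0.04, "493.9")
    _emit(rng.random(n) < 0.03, "715.9")
    _emit(rng.random(n) < 0.02, "365.9")
    _emit(rng.random(n) < 0.03, "599.7", times=1)  # single occurrence: missing
    _emit(rng.random(n) < 0.01, "799.9", times=1)  # unmapped code
    icd9 = np.array([";".join(c) for c in codes], dtype=object)
    dm_codes = np.where(diabetes, "250.00", "").astype(object)

    phenotypes = pd.DataFrame({
        "participant_id": pid, "cohort": spec.name, "age": age, "sex": sex,
        "creatinine_mg_dl": creat_str, "icd9_codes": icd9,
        "rrt_flag": rrt.astype(int), "diabetes_codes": dm_codes, "batch": batch,
        "apol1_g1": g1, "apol1_g2": g2, "black_indicator": black.astype(int),
    })

    rare = RareGenotypes(
        variants=var[["variant_id", "gene", "chrom", "pos", "ref", "alt"]].copy(),
        samples=pid, gt=gt, gq=gq, dp=dp, sex=sex,
    )

    # --- truth carrier flags over variants that survive the filters ---
    surv = _surviving_mask(rare, var, config)
    gtp = np.maximum(gt, 0)
    for gene_set, genes in GENE_SETS.items():
        in_set = var["gene"].isin(genes).to_numpy()
        for model in ("m1", "m2", "m3"):
            cols = in_set & var[f"qv_{model}"].to_numpy() & surv
            truth[f"carrier_{gene_set}_{model}"] = (gtp[:, cols] > 0).any(axis=1)

    male = sex == "M"
    rec = np.zeros(n, dtype=bool)
    m3_cols = var["qv_m3"].to_numpy() & surv
    genes_v = var["gene"].to_numpy()
    chrom_v = var["chrom"].to_numpy()
    hom_cols = m3_cols & ~(chrom_v == "X")
    rec |= (gtp[:, hom_cols] == 2).any(axis=1)
    for gene in ("COL4A3", "COL4A4"):
        cset = m3_cols & (genes_v == gene)
        rec |= (gtp[:, cset] > 0).sum(axis=1) >= 2
    hemi_cols = m3_cols & (genes_v == "COL4A5")
    rec |= male & (gtp[:, hemi_cols] > 0).any(axis=1)
    truth["recessive_col4a_m3"] = rec

    truth["liability_carrier"] = analysis_carriers
    truth["gps_std_true"] = gps_std
    truth["apol1_risk"] = apol1_risk
    truth["diabetes"] = diabetes
    truth["disease"] = disease
    truth["label"] = label
    truth["egfr_target"] = target
    truth["in_cis_pair"] = False
    truth.loc[planted["in_cis"], "in_cis_pair"] = True

    return SimulatedCohort(
        name=spec.name, phenotypes=phenotypes, rare=rare,
        annotation=annotation.copy(), dosages=dosages,
        dosage_variant_ids=cv_ids, truth=truth,
    )


def _surviving_mask(rare: RareGenotypes, var: pd.DataFrame, config: SimConfig):
    """Which planted variants survive the QC cascade in this cohort, computed
    from the generative record (the oracle for filter tests)."""
    bad = (rare.gq <= 90) | (rare.dp <= 10)
    gt_masked = np.where(bad, -1, rare.gt)
    has_alt = (gt_masked > 0).any(axis=0)

    thr = var["gene"].map(config.maf_thresholds).to_numpy(dtype=float)
    af_cols = [c for c in var.columns if c.startswith("af_")]
    db_af = var[af_cols].to_numpy(dtype=float)
    db_ok = np.nanmax(db_af, axis=1) <= thr

    tmp = RareGenotypes(variants=rare.variants, samples=rare.samples,
                        gt=gt_masked.astype(np.int8), sex=rare.sex)
    ac, an = tmp.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_af = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    obs_ok = obs_af <= thr

    not_syn = var["true_class"].to_numpy() != "synonymous"
    return has_alt & db_ok & obs_ok & not_syn
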