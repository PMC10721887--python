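"""File-format plumbing: VCF 4.2 with GT/GQ/DP, TSV tables, YAML config.

Writers are deterministic (fixed column order, fixed float formatting) so a
fixed-seed run is byte-identical.  VCF reading goes through cyvcf2 and is
only imported when used, keeping the numeric core import-light.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .filtering import RareGenotypes

__all__ = ["write_vcf", "read_vcf", "write_study", "read_truth"]


def write_vcf(rare: RareGenotypes, path: str):
    """Plain-text VCF 4.2 with GT:GQ:DP; male X calls written haploid-as-
    homozygous (1/1)."""
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(rare.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in rare.samples) + "\n")
        gq = rare.gq if rare.gq is not None else np.full_like(rare.gt, 99)
        dp = rare.dp if rare.dp is not None else np.full_like(rare.gt, 30)
        for j, row in rare.variants.iterrows():
            calls = "\t".join(
                f"{gt_strings[int(g)]}:{int(q)}:{int(d)}"
                for g, q, d in zip(rare.gt[:, j], gq[:, j], dp[:, j])
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT:GQ:DP\t{calls}\n"
            )


def read_vcf(path: str, gene_map: dict | None = None, sex=None) -> RareGenotypes:
    """Read a VCF into a :class:`RareGenotypes` (requires cyvcf2).

    ``gene_map`` maps variant id -> gene (defaults to the id's prefix before
    '_').  Multi-allelic records must be pre-split.  Raises if GQ or DP is
    absent on any record.
    """
    from cyvcf2 import VCF  # heavyweight optional dependency

    vcf = VCF(path)
    samples = np.array(vcf.samples)
    var_rows, gts, gqs, dps = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
        try:
            gq = rec.format("GQ").reshape(-1)
            dp = rec.format("DP").reshape(-1)
        except Exception as exc:
            raise ValueError(f"missing GQ/DP on record {vid}") from exc
        gene = (gene_map or {}).get(vid, vid.split("_")[0])
        var_rows.append({"variant_id": vid, "gene": gene, "chrom": rec.CHROM,
                         "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]})
        g = np.asarray(rec.genotypes)[:, :2]
        gt = np.where((g < 0).any(axis=1), -1, (g > 0).sum(axis=1)).astype(np.int8)
        gts.append(gt)
        gqs.append(gq.astype(np.int16))
        dps.append(dp.astype(np.int16))
    variants = pd.DataFrame(var_rows)
    return RareGenotypes(
        variants=variants, samples=samples,
        gt=np.array(gts, dtype=np.int8).T,
        gq=np.array(gqs, dtype=np.int16).T,
        dp=np.array(dps, dtype=np.int16).T,
        sex=None if sex is None else np.asarray(sex),
    )


def _write_tsv(df: pd.DataFrame, path: str):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_study(study, outdir: str):
    """Write every artifact of a simulated study in its standard text format."""
    os.makedirs(outdir, exist_ok=True)
    _write_tsv(study.weights, os.path.join(outdir, "weights.tsv"))
    study.phecode_map.to_csv(os.path.join(outdir, "phecode_map.csv"), index=False)
    _write_tsv(study.truth_variants, os.path.join(outdir, "truth_variants.tsv"))

    panel = pd.DataFrame(study.panel_dosages, columns=study.panel_variant_ids)
    panel.insert(0, "sample_id", study.panel_samples)
    panel.insert(1, "ancestry", study.panel_labels)
    _write_tsv(panel, os.path.join(outdir, "reference_panel.tsv"))

    cfg = asdict(study.config)
    for c in cfg["cohorts"]:
        c["age_range"] = [int(x) for x in c["age_range"]]
    with open(os.path.join(outdir, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    for name, cohort in study.cohorts.items():
        cdir = os.path.join(outdir, name)
        os.makedirs(cdir, exist_ok=True)
        write_vcf(cohort.rare, os.path.join(cdir, "rare_variants.vcf"))
        _write_tsv(cohort.annotation, os.path.join(cdir, "annotation.tsv"))
        _write_tsv(cohort.phenotypes, os.path.join(cdir, "phenotypes.tsv"))
        _write_tsv(cohort.truth, os.path.join(cdir, "truth_participants.tsv"))
        dos = pd.DataFrame(cohort.dosages, columns=cohort.dosage_variant_ids)
        dos.insert(0, "participant_id", cohort.phenotypes["participant_id"].to_numpy())
        _write_tsv(dos, os.path.join(cdir, "common_dosages.tsv"))


def load_study(outdir: str):
    """Reload a study directory written by :func:`write_study`.

    Reconstructs the in-memory study from the text artifacts (VCF genotypes,
    annotation, phenotypes, dosages, panel, weights, map, truth).
    """
    from .simulate import SimConfig, CohortSpec, SimulatedCohort, SimulatedStudy

    with open(os.path.join(outdir, "sim_config.yaml")) as fh:
        raw_cfg = yaml.safe_load(fh)
    raw_cfg["cohorts"] = [CohortSpec(**{**c, "age_range": tuple(c["age_range"])})
                          for c in raw_cfg["cohorts"]]
    config = SimConfig(**raw_cfg)

    weights = pd.read_csv(os.path.join(outdir, "weights.tsv"), sep="\t")
    phecode_map = pd.read_csv(os.path.join(outdir, "phecode_map.csv"))
    truth_variants = pd.read_csv(os.path.join(outdir, "truth_variants.tsv"), sep="\t")
    panel = pd.read_csv(os.path.join(outdir, "reference_panel.tsv"), sep="\t")
    panel_samples = panel["sample_id"].to_numpy()
    panel_labels = panel["ancestry"].to_numpy()
    cv_ids = np.array(panel.columns[2:])
    panel_dos = panel.iloc[:, 2:].to_numpy(dtype=np.int8)

    cohorts = {}
    for spec in config.cohorts:
        cdir = os.path.join(outdir, spec.name)
        pheno = pd.read_csv(os.path.join(cdir, "phenotypes.tsv"), sep="\t",
                            dtype={"creatinine_mg_dl": str})
        sex = pheno["sex"].to_numpy()
        rare = read_vcf(os.path.join(cdir, "rare_variants.vcf"), sex=sex)
        annot = pd.read_csv(os.path.join(cdir, "annotation.tsv"), sep="\t")
        truth = pd.read_csv(os.path.join(cdir, "truth_participants.tsv"), sep="\t")
        dos = pd.read_csv(os.path.join(cdir, "common_dosages.tsv"), sep="\t")
        cohorts[spec.name] = SimulatedCohort(
            name=spec.name, phenotypes=pheno, rare=rare, annotation=annot,
            dosages=dos.iloc[:, 1:].to_numpy(dtype=np.int8),
            dosage_variant_ids=np.array(dos.columns[1:]), truth=truth,
        )
    return SimulatedStudy(
        config=config, cohorts=cohorts, weights=weights,
        panel_dosages=panel_dos, panel_labels=panel_labels,
        panel_samples=panel_samples, panel_variant_ids=cv_ids,
        phecode_map=phecode_map, truth_variants=truth_variants,
    )


def read_truth(outdir: str) -> dict:
    """Round-trip the truth record written by :func:`write_study`."""
    with open(os.path.join(outdir, "sim_config.yaml")) as fh:
        cfg = yaml.safe_load(fh)
    out = {"config": cfg,
           "variants": pd.read_csv(os.path.join(outdir, "truth_variants.tsv"), sep="\t")}
    for name in sorted(os.listdir(outdir)):
        p = os.path.join(outdir, name, "truth_participants.tsv")
        if os.path.isfile(p):
            out[name] = pd.read_csv(p, sep="\t")
    return out
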