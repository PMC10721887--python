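"""Gene panel and consequence vocabulary for the monogenic kidney-disease analysis.

The panel covers the two autosomal dominant polycystic kidney disease (ADPKD)
genes and the three collagen-IV nephropathy (COL4A-AN) genes.  COL4A5 is
X-linked; male carriers are hemizygous.
"""

from __future__ import annotations

#: gene -> chromosome.  COL4A5 is the only X-linked gene in the panel.
GENE_CHROMOSOME: dict[str, str] = {
    "PKD1": "16",
    "PKD2": "4",
    "COL4A3": "2",
    "COL4A4": "2",
    "COL4A5": "X",
}

ADPKD_GENES = ("PKD1", "PKD2")
COL4A_GENES = ("COL4A3", "COL4A4", "COL4A5")

GENE_SETS: dict[str, tuple[str, ...]] = {
    "adpkd": ADPKD_GENES,
    "col4a": COL4A_GENES,
}

#: rare-variant frequency ceilings: ADPKD genes are held to an ultra-rare
#: threshold (dominant inheritance), COL4A genes to a rare threshold
#: (the severest COL4A-AN phenotypes are recessive).
DEFAULT_MAF_THRESHOLDS: dict[str, float] = {
    "PKD1": 1e-5,
    "PKD2": 1e-5,
    "COL4A3": 1e-3,
    "COL4A4": 1e-3,
    "COL4A5": 1e-3,
}

#: predicted loss-of-function consequence classes.  "essential_splice" is an
#: accepted alias for the two essential splice-site classes; "splice_region"
#: (non-essential) is deliberately NOT loss-of-function.
PLOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift",
        "stop_lost",
        "start_lost",
        "splice_acceptor",
        "splice_donor",
        "essential_splice",
    }
)

#: closed consequence vocabulary accepted on input.
CONSEQUENCE_VOCABULARY = frozenset(
    PLOF_CONSEQUENCES
    | {"missense", "synonymous", "splice_region", "inframe_deletion", "inframe_insertion"}
)

#: the five missense in-silico predictors whose unanimous "damaging" verdict,
#: together with a REVEL score > 0.70, defines a deleterious missense variant.
PREDICTOR_COLUMNS = (
    "sift",
    "polyphen2_hdiv",
    "polyphen2_hvar",
    "lrt",
    "mutation_taster",
)

REVEL_THRESHOLD = 0.70

#: clinical assertion vocabulary (ClinVar / Varsome style).
ASSERTION_VOCABULARY = frozenset({"P", "LP", "B", "LB", "VUS", "none"})

ANCESTRIES = ("EUR", "AFR", "EAS", "SAS", "AMR")

#: allele-frequency sources tabulated in the annotation table.
AF_SOURCES = ("cohort1", "cohort2", "gnomad")


def gene_set_for(gene: str) -> str:
    """Return 'adpkd' or 'col4a' for a panel gene; raise for unknown genes."""
    if gene in ADPKD_GENES:
        return "adpkd"
    if gene in COL4A_GENES:
        return "col4a"
    raise ValueError(f"unknown gene: {gene!r}")
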