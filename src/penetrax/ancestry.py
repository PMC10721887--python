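"""Ancestry and relatedness: LD pruning, reference-projected principal
components, random-forest continental ancestry assignment, and KING-robust
kinship with greedy relatedness exclusion.

The reference decomposition is fixed once (computed on the labeled panel,
emulating a 1000 Genomes-style reference); study samples are mapped by
loading projection and never refit, so cohort structure cannot distort the
reference axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "ld_prune",
    "PCProjector",
    "project_pcs",
    "classify_ancestry",
    "king_kinship",
    "exclude_related",
]


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between variant columns."""
    x = dosages.astype(np.float64)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    r = c / np.outer(sd, sd)
    return r**2


def ld_prune(
    dosages: np.ndarray,
    window: int = 500,
    step: int = 50,
    r2_threshold: float = 0.05,
) -> np.ndarray:
    """Sliding-window pairwise LD pruning (variant-count windows).

    Within each window of ``window`` variants advanced by ``step``, while any
    kept pair has r^2 > threshold the later variant of the pair (input order)
    is removed.  Returns the sorted indices of kept variants.  Monomorphic
    variants are removed first with a warning.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("require 0 < r2_threshold < 1")
    dosages = np.asarray(dosages)
    m = dosages.shape[1]
    sd = dosages.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"removed {int((~keep).sum())} monomorphic variant(s) before pruning")
    idx = np.flatnonzero(keep)

    r2 = _pairwise_r2(dosages[:, idx])
    kept = np.ones(len(idx), dtype=bool)
    start = 0
    while start < len(idx):
        stop = min(start + window, len(idx))
        win = np.arange(start, stop)
        for a_pos in range(len(win)):
            i = win[a_pos]
            if not kept[i]:
                continue
            for b_pos in range(a_pos + 1, len(win)):
                j = win[b_pos]
                if kept[j] and r2[i, j] > r2_threshold:
                    kept[j] = False  # drop the later variant: deterministic
        if stop == len(idx):
            break
        start += step
    return idx[kept]


@dataclass
class PCProjector:
    """PCA fitted on a reference panel; cohort samples are projected onto the
    fixed reference axes (no refitting).

    Genotypes are centered at 2p and scaled by sqrt(2p(1-p)) with allele
    frequencies estimated from the reference.
    """

    n_pcs: int = 10
    min_shared_variants: int = 100

    def fit(self, ref_dosages: np.ndarray, variant_ids=None) -> "PCProjector":
        x = np.asarray(ref_dosages, dtype=np.float64)
        if x.shape[1] < self.min_shared_variants:
            raise ValueError(
                f"need >= {self.min_shared_variants} shared variants, got {x.shape[1]}"
            )
        p = x.mean(axis=0) / 2.0
        scale = np.sqrt(2.0 * p * (1.0 - p))
        scale[scale == 0] = 1.0
        self.mean_ = 2.0 * p
        self.scale_ = scale
        self.variant_ids_ = None if variant_ids is None else np.asarray(variant_ids)
        z = (x - self.mean_) / self.scale_
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        k = min(self.n_pcs, len(s))
        self.loadings_ = vt[:k].T  # (m, k)
        self.singular_values_ = s[:k]
        self.reference_pcs_ = u[:, :k] * s[:k]
        return self

    def transform(self, dosages: np.ndarray) -> np.ndarray:
        z = (np.asarray(dosages, dtype=np.float64) - self.mean_) / self.scale_
        return z @ self.loadings_


def project_pcs(
    ref_dosages: np.ndarray,
    cohort_dosages: np.ndarray,
    n_pcs: int = 10,
    variant_ids=None,
) -> tuple[np.ndarray, np.ndarray, PCProjector]:
    """Fit reference PCs and project cohort samples onto them.

    Both matrices must be over the same variants in the same order (e.g. the
    LD-pruned shared set).  Returns (reference PCs, cohort PCs, projector).
    """
    if ref_dosages.shape[1] != cohort_dosages.shape[1]:
        raise ValueError("reference and cohort must share the same variant columns")
    proj = PCProjector(n_pcs=n_pcs).fit(ref_dosages, variant_ids)
    return proj.reference_pcs_, proj.transform(cohort_dosages), proj


def classify_ancestry(
    ref_pcs: np.ndarray,
    ref_labels: np.ndarray,
    cohort_pcs: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    uncertain_below: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Random-forest continental ancestry assignment trained on the labeled
    reference PCs only.

    Returns (per-sample DataFrame with label / probability / uncertain flag,
    held-out reference accuracy).
    """
    ref_labels = np.asarray(ref_labels)
    classes = np.unique(ref_labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 ancestry classes in the reference")

    tr_x, te_x, tr_y, te_y = train_test_split(
        ref_pcs, ref_labels, test_size=0.2, random_state=seed, stratify=ref_labels
    )
    holdout_rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    holdout_rf.fit(tr_x, tr_y)
    heldout_accuracy = float((holdout_rf.predict(te_x) == te_y).mean())

    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(ref_pcs, ref_labels)
    probs = rf.predict_proba(cohort_pcs)
    best = probs.argmax(axis=1)
    out = pd.DataFrame(
        {
            "ancestry": rf.classes_[best],
            "probability": probs[np.arange(len(best)), best],
        }
    )
    out["uncertain"] = out["probability"] < uncertain_below
    return out, heldout_accuracy


def king_kinship(
    dosages: np.ndarray, sample_ids=None, min_kinship: float | None = None
) -> pd.DataFrame:
    """Pairwise kinship by the KING robust between-family moment estimator.

    For samples i, j with per-pair counts over non-missing biallelic sites
    (dosage -1 = missing): N_Aa,Aa (both heterozygous), N_AA,aa (opposite
    homozygotes), and per-sample heterozygote counts N_Aa^(i), N_Aa^(j):

        phi_ij = (N_Aa,Aa - 2 N_AA,aa) / (2 min(N_Aa^(i), N_Aa^(j)))
                 + 1/2 - (N_Aa^(i) + N_Aa^(j)) / (4 min(N_Aa^(i), N_Aa^(j)))

    Robust to population structure because no allele frequencies enter.
    Returns the upper-triangle pair list (id1, id2, kinship); optionally only
    pairs with kinship > ``min_kinship``.
    """
    g = np.asarray(dosages)
    n = g.shape[0]
    called = (g >= 0).astype(np.float64)
    het = ((g == 1) & (g >= 0)).astype(np.float64)
    aa = (g == 0).astype(np.float64)
    bb = (g == 2).astype(np.float64)

    n_hethet = het @ het.T
    n_opp = aa @ bb.T + bb @ aa.T
    # heterozygote counts restricted to sites called in BOTH members of a pair
    het_i = het @ called.T  # het in i among sites called in j
    het_j = called @ het.T
    het_min = np.minimum(het_i, het_j)

    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / (2.0 * het_min) + 0.5 - (
            het_i + het_j
        ) / (4.0 * het_min)

    ids = np.asarray(sample_ids) if sample_ids is not None else np.arange(n)
    iu, ju = np.triu_indices(n, k=1)
    out = pd.DataFrame({"id1": ids[iu], "id2": ids[ju], "kinship": phi[iu, ju]})
    if min_kinship is not None:
        out = out.loc[out["kinship"] > min_kinship].reset_index(drop=True)
    return out


def exclude_related(
    kinship_pairs: pd.DataFrame, threshold: float = 0.0442, sample_ids=None
) -> set:
    """Greedy relatedness pruning: repeatedly drop the member with the most
    remaining related partners (ties broken by dropping the lexicographically
    later id) until no kept pair exceeds the threshold.

    Returns the kept participant set (all ids if ``sample_ids`` given, else
    all ids appearing in the pair list).
    """
    over = kinship_pairs.loc[kinship_pairs["kinship"] > threshold]
    adjacency: dict = {}
    for a, b in zip(over["id1"], over["id2"]):
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    degrees = {k: len(v) for k, v in adjacency.items()}
    dropped = set()
    while True:
        active = [(d, str(k), k) for k, d in degrees.items() if d > 0]
        if not active:
            break
        _, _, victim = max(active)  # most relatives; tie -> later id
        dropped.add(victim)
        degrees[victim] = 0
        for nb in adjacency[victim]:
            if nb not in dropped and degrees[nb] > 0:
                degrees[nb] -= 1

    if sample_ids is not None:
        universe = set(np.asarray(sample_ids).tolist())
    else:
        universe = set(kinship_pairs["id1"]).union(kinship_pairs["id2"])
    return universe - dropped
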