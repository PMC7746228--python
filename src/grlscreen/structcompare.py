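"""Rigid-body superposition, RMSD, and TM-score fold comparison.

Given two C-alpha coordinate sets and a residue correspondence (from a
sequence alignment or an explicit index map — no structural alignment
search is performed), the Kabsch algorithm gives the least-squares optimal
rotation/translation, and the TM-score summarises fold agreement on a
length-normalized [0,1] scale:

    TM = (1/L_ref) * sum_i 1 / (1 + (d_i/d0)^2),
    d0 = 1.24 * (L_ref - 15)^(1/3) - 1.8   (floored at 0.5 A)

with the standard iterative subset refinement (re-superpose on pairs
closer than 2*d0 until a fixed point).  Scores of 0.0-0.30 indicate random
structural similarity, 0.5-1.00 a shared global fold, 1.00 a perfect
match; the band in between is reported as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from grlscreen.io import CoordinateSet, ValidationError

TM_RANDOM_MAX = 0.30
TM_SAME_FOLD_MIN = 0.50
D0_FLOOR = 0.5
MAX_REFINE_ITERATIONS = 20


@dataclass(frozen=True)
class StructureComparison:
    """One pairwise structure comparison and its fold classification."""

    id1: str
    id2: str
    n_aligned: int
    rmsd: float
    tm_score: float
    classification: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValidationError(f"TM-score {self.tm_score} outside [0,1]")
        if self.rmsd < 0:
            raise ValidationError("rmsd must be non-negative")
        if self.classification != _classify_score(self.tm_score):
            raise ValidationError("classification inconsistent with TM-score")


def kabsch_superpose(
    a: CoordinateSet | np.ndarray,
    b: CoordinateSet | np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of b onto a.

    ``correspondence`` lists (index_in_a, index_in_b) positional pairs
    (0-based into the coordinate arrays); None means identity over the
    common length.  Returns (rotation, translation, rmsd) such that
    ``b @ rotation.T + translation`` best matches a; reflections are
    excluded by the determinant sign correction.
    """
    pa = a.coords if isinstance(a, CoordinateSet) else np.asarray(a, float)
    pb = b.coords if isinstance(b, CoordinateSet) else np.asarray(b, float)
    if correspondence is None:
        n = min(len(pa), len(pb))
        correspondence = [(i, i) for i in range(n)]
    if len(correspondence) < 3:
        raise ValidationError("superposition needs at least 3 corresponding pairs")
    ia = np.array([i for i, _ in correspondence])
    ib = np.array([j for _, j in correspondence])
    P = pa[ia]
    Q = pb[ib]
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    correction = np.diag([1.0, 1.0, d])
    R = Vt.T @ correction @ U.T
    t = cp - R @ cq
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return R, t, rmsd


def tm_d0(l_ref: int) -> float:
    """Length-dependent distance scale d0 of the TM-score."""
    if l_ref < 16:
        raise ValidationError(f"TM-score reference length must be >= 16, got {l_ref}")
    return max(1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8, D0_FLOOR)


def tm_score(
    a: CoordinateSet | np.ndarray,
    b: CoordinateSet | np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
    l_ref: int | None = None,
) -> float:
    """TM-score of b against a under a fixed correspondence.

    The superposition is seeded on the full correspondence and iteratively
    refined on the subset of pairs with d_i < 2*d0 (fixed point or 20
    iterations); the reported score is the maximum over iterations,
    normalized by ``l_ref`` (default: the number of residues in a).
    """
    pa = a.coords if isinstance(a, CoordinateSet) else np.asarray(a, float)
    pb = b.coords if isinstance(b, CoordinateSet) else np.asarray(b, float)
    if correspondence is None:
        n = min(len(pa), len(pb))
        correspondence = [(i, i) for i in range(n)]
    if l_ref is None:
        l_ref = len(pa)
    d0 = tm_d0(l_ref)
    pairs = list(correspondence)
    subset = pairs
    best = 0.0
    prev_subset: set[tuple[int, int]] | None = None
    for _ in range(MAX_REFINE_ITERATIONS):
        if len(subset) < 3:
            break
        R, t, _ = kabsch_superpose(pa, pb, subset)
        ia = np.array([i for i, _ in pairs])
        ib = np.array([j for _, j in pairs])
        moved = pb[ib] @ R.T + t
        dists = np.sqrt(np.sum((moved - pa[ia]) ** 2, axis=1))
        score = float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)) / l_ref)
        best = max(best, score)
        new_subset = [p for p, dist in zip(pairs, dists) if dist < 2 * d0]
        key = set(new_subset)
        if prev_subset is not None and key == prev_subset:
            break
        prev_subset = key
        subset = new_subset
    return best


def _classify_score(tm: float) -> str:
    if tm <= TM_RANDOM_MAX:
        return "random"
    if tm >= TM_SAME_FOLD_MIN:
        return "same_fold"
    return "ambiguous"


def classify(comparison: StructureComparison) -> str:
    """Fold-class label of a comparison (random / ambiguous / same_fold)."""
    return comparison.classification


def compare_structures(
    a: CoordinateSet,
    b: CoordinateSet,
    correspondence: Sequence[tuple[int, int]] | None = None,
    l_ref: int | None = None,
) -> StructureComparison:
    """Superpose, score, and classify one structure pair."""
    if correspondence is None:
        n = min(len(a), len(b))
        correspondence = [(i, i) for i in range(n)]
    _, _, rmsd = kabsch_superpose(a, b, correspondence)
    tm = tm_score(a, b, correspondence, l_ref)
    return StructureComparison(
        id1=a.id,
        id2=b.id,
        n_aligned=len(correspondence),
        rmsd=rmsd,
        tm_score=tm,
        classification=_classify_score(tm),
    )


def intake_filter(
    metadata: dict,
    *,
    min_msa_sequences: int = 15,
    min_estimated_tm: float = 0.17,
) -> bool:
    """Model-intake filter for predicted structures.

    A model is admitted unless its metadata reports an MSA of fewer than
    ``min_msa_sequences`` sequences or an estimated TM-score below
    ``min_estimated_tm`` (both signs of an unreliable prediction); absent
    fields do not exclude.
    """
    n_seqs = metadata.get("msa_sequences")
    if n_seqs is not None and n_seqs < min_msa_sequences:
        return False
    est = metadata.get("estimated_tm_score")
    if est is not None and est < min_estimated_tm:
        return False
    return True


def pairwise_structure_matrix(
    sets: Sequence[CoordinateSet],
    correspondences: dict[tuple[str, str], Sequence[tuple[int, int]]] | None = None,
):
    """TM-score and RMSD matrices over a collection.

    Returns ``(tm, rmsd)`` DataFrames.  The RMSD matrix is symmetric; the
    TM-score matrix normalizes each entry by the *row* structure's length,
    so both orientations of every pair are reported and the matrix may be
    asymmetric.  ``correspondences`` maps unordered id pairs to positional
    pairs; missing pairs use the identity correspondence.
    """
    import pandas as pd

    ids = [cs.id for cs in sets]
    n = len(sets)
    tm = np.ones((n, n))
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            corr = None
            if correspondences:
                corr = correspondences.get((ids[i], ids[j])) or [
                    (b, a) for a, b in correspondences.get((ids[j], ids[i]), [])
                ] or None
            if corr is None:
                m = min(len(sets[i]), len(sets[j]))
                corr = [(k, k) for k in range(m)]
            _, _, r = kabsch_superpose(sets[i], sets[j], corr)
            rmsd[i, j] = rmsd[j, i] = r
            tm[i, j] = tm_score(sets[i], sets[j], corr, l_ref=len(sets[i]))
            corr_rev = [(b, a) for a, b in corr]
            tm[j, i] = tm_score(sets[j], sets[i], corr_rev, l_ref=len(sets[j]))
    return (
        pd.DataFrame(tm, index=ids, columns=ids),
        pd.DataFrame(rmsd, index=ids, columns=ids),
    )
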