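"""Per-family sequence profiles and all-vs-all profile similarity.

Family MSAs are condensed into pseudocounted position-probability profiles
(no insert/delete states), pairs of profiles are locally aligned with a
log-odds co-emission score, and the resulting normalized similarities form
a symmetric matrix that can be hierarchically clustered.  This is the
desk-scale analogue of comparing profile HMMs of candidate families with a
remote-homology tool: the matrix structure and the within/between-family
contrast are reproduced, the absolute "probabilities" are a declared
calibration of this package, not those of any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from grlscreen.io import AMINO_ACIDS, ValidationError

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")

# Logistic calibration of the per-column alignment score (bits/column):
# self-alignments of real profiles sit well above the midpoint (~3.5-4),
# alignments between unrelated families — which still share membrane-protein
# composition, hence score ~1-1.3 against a uniform background — fall well
# below (see docs/methods.md).
LOGISTIC_MIDPOINT = 2.0
LOGISTIC_STEEPNESS = 4.0
MIN_EFFECTIVE_COLUMNS = 30

DEFAULT_GAP_OPEN = 3.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class SequenceProfile:
    """Position-probability profile over the 20 amino acids."""

    id: str
    columns: np.ndarray  # (length, 20), rows sum to 1
    n_sequences: int

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != 20 or cols.shape[0] == 0:
            raise ValidationError(f"{self.id}: columns must be a non-empty (L, 20) array")
        if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"{self.id}: profile columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.columns.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric all-vs-all profile similarity in [0,1], unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValidationError("similarity matrix shape must match ids")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValidationError("similarities must lie in [0,1]")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
            raise ValidationError("similarity diagonal must be 1")


def build_profile(
    msa: Sequence[tuple[str, str]],
    *,
    profile_id: str = "profile",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> SequenceProfile:
    """Condense an aligned family into a pseudocounted profile.

    ``msa`` is a list of (id, gapped sequence) pairs of equal length.
    Columns with more than ``max_gap_fraction`` gaps are dropped; each
    retained column's probabilities are
    ``(counts + pseudocount * background) / (n_nongap + pseudocount)``.
    """
    if len(msa) < 2:
        raise ValidationError("a profile needs at least 2 aligned sequences")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValidationError(f"aligned sequences have unequal lengths {sorted(lengths)}")
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValidationError("background must be a 20-vector summing to 1")

    length = lengths.pop()
    columns = []
    for j in range(length):
        letters = [s[j] for _, s in msa]
        n_gap = sum(c in GAP_CHARS for c in letters)
        if n_gap / len(letters) > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in letters:
            if c in AA_INDEX:  # gaps and X contribute nothing
                counts[AA_INDEX[c]] += 1
        n = counts.sum()
        if n == 0:
            continue
        columns.append((counts + pseudocount * background) / (n + pseudocount))
    if not columns:
        raise ValidationError("no columns retained after gap filtering")
    return SequenceProfile(id=profile_id, columns=np.array(columns), n_sequences=len(msa))


def _column_scores(p1: SequenceProfile, p2: SequenceProfile, background: np.ndarray) -> np.ndarray:
    """Log2-odds co-emission score for every column pair, shape (L1, L2)."""
    weighted = p2.columns / background  # (L2, 20)
    co = p1.columns @ weighted.T
    return np.log2(np.maximum(co, 1e-12))


def align_profiles(
    p1: SequenceProfile,
    p2: SequenceProfile,
    *,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    background: np.ndarray | None = None,
) -> tuple[float, float]:
    """Local profile-profile alignment; returns (score, normalized similarity).

    Smith-Waterman over column pairs with affine gaps.  The similarity is a
    logistic transform of the per-column score of the best local alignment,
    with the column count floored at MIN_EFFECTIVE_COLUMNS so that short
    chance alignments between unrelated profiles normalize low while
    full-length self-alignments normalize to ~1.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    S = _column_scores(p1, p2, np.asarray(background, dtype=float))
    L1, L2 = S.shape
    NEG = -1e18
    # Gotoh local alignment: M = match state, X/Y = gap-in-p2 / gap-in-p1.
    # C* matrices carry the number of match columns on each state's best path.
    M = np.zeros((L1 + 1, L2 + 1))
    X = np.full((L1 + 1, L2 + 1), NEG)
    Y = np.full((L1 + 1, L2 + 1), NEG)
    CM = np.zeros((L1 + 1, L2 + 1), dtype=int)
    CX = np.zeros((L1 + 1, L2 + 1), dtype=int)
    CY = np.zeros((L1 + 1, L2 + 1), dtype=int)
    best_score = 0.0
    n_cols = 0
    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_extend:
                X[i, j], CX[i, j] = M[i - 1, j] - gap_open, CM[i - 1, j]
            else:
                X[i, j], CX[i, j] = X[i - 1, j] - gap_extend, CX[i - 1, j]
            if M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_extend:
                Y[i, j], CY[i, j] = M[i, j - 1] - gap_open, CM[i, j - 1]
            else:
                Y[i, j], CY[i, j] = Y[i, j - 1] - gap_extend, CY[i, j - 1]
            prev_val = M[i - 1, j - 1]
            prev_cols = CM[i - 1, j - 1]
            if X[i - 1, j - 1] > prev_val:
                prev_val, prev_cols = X[i - 1, j - 1], CX[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev_val:
                prev_val, prev_cols = Y[i - 1, j - 1], CY[i - 1, j - 1]
            m = S[i - 1, j - 1] + prev_val
            if m > 0:
                M[i, j], CM[i, j] = m, prev_cols + 1
            else:
                M[i, j], CM[i, j] = 0.0, 0
            if M[i, j] > best_score:
                best_score = float(M[i, j])
                n_cols = int(CM[i, j])
    if n_cols == 0:
        return 0.0, 0.0
    per_column = best_score / max(n_cols, MIN_EFFECTIVE_COLUMNS)
    similarity = 1.0 / (1.0 + np.exp(-LOGISTIC_STEEPNESS * (per_column - LOGISTIC_MIDPOINT)))
    return float(best_score), float(similarity)


def all_vs_all(profiles: Sequence[SequenceProfile], **align_kwargs) -> SimilarityMatrix:
    """Symmetric all-vs-all similarity matrix with unit diagonal.

    Off-diagonal entries are align_profiles similarities (the pair is
    computed once; the score is symmetric by construction of the column
    scores); the diagonal is 1 by definition.
    """
    if len(profiles) < 2:
        raise ValidationError("all_vs_all needs at least 2 profiles")
    ids = tuple(p.id for p in profiles)
    if len(set(ids)) != len(ids):
        raise ValidationError("profile ids must be unique")
    n = len(profiles)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, sim = align_profiles(profiles[i], profiles[j], **align_kwargs)
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(ids=ids, values=values)


def cluster(matrix: SimilarityMatrix, method: str = "average"):
    """Average-linkage hierarchical clustering over distance 1 - similarity.

    Returns the scipy linkage matrix; leaf order on ties is deterministic
    because scipy's agglomeration scans pairs in index order and the input
    ids fix the index order.
    """
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method=method)


def cluster_newick(matrix: SimilarityMatrix, method: str = "average") -> str:
    """Newick rendering of the clustering dendrogram (branch lengths = heights)."""
    Z = cluster(matrix, method=method)
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{matrix.ids[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return render(tree, tree.dist) + ";"
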