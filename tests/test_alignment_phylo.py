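"""Global alignment, identity statistics, progressive MSA, neighbor joining."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from grlscreen.alignment_phylo import (
    distance_matrix,
    global_align,
    identity_matrix,
    min_identity,
    nj_tree,
    progressive_msa,
)
from grlscreen.io import ProteinRecord, ValidationError
from grlscreen.synthetic_data import GrlGeneratorSpec, make_family

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignment_score(s1, s2, gap_open=11.0, gap_extend=1.0):
    """Brute-force optimal global score: enumerate all gapped alignments.

    Exponential; for oracle use on sequences of length <= 8 only.  The
    affine gap cost of a finished alignment is computed from its gap runs,
    independently of any DP recurrence.
    """

    def score_of(a1, a2):
        total = 0.0
        for row in (a1, a2):
            in_gap = False
            for c in row:
                if c == "-":
                    total -= gap_extend if in_gap else gap_open
                    in_gap = True
                else:
                    in_gap = False
        for x, y in zip(a1, a2):
            if x != "-" and y != "-":
                total += BLOSUM62[x, y]
        return total

    best = -np.inf
    stack = [("", "", 0, 0)]
    while stack:
        a1, a2, i, j = stack.pop()
        if i == len(s1) and j == len(s2):
            best = max(best, score_of(a1, a2))
            continue
        if i < len(s1) and j < len(s2):
            stack.append((a1 + s1[i], a2 + s2[j], i + 1, j + 1))
        if i < len(s1):
            stack.append((a1 + s1[i], a2 + "-", i + 1, j))
        if j < len(s2):
            stack.append((a1 + "-", a2 + s2[j], i, j + 1))
    return best


class TestGlobalAlign:
    def test_identical_sequences(self):
        a = global_align(ProteinRecord(id="1", sequence="ACDEFG"),
                         ProteinRecord(id="2", sequence="ACDEFG"))
        assert a.identity_pct == 100.0
        assert "-" not in a.aligned1 + a.aligned2

    def test_single_mismatch_identity(self):
        a = global_align(ProteinRecord(id="1", sequence="AAAA"),
                         ProteinRecord(id="2", sequence="AAGA"))
        assert a.identity_pct == 75.0

    def test_score_matches_bruteforce_on_short_pairs(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            s1 = "".join(rng.choice(aa, size=rng.integers(3, 7)))
            s2 = "".join(rng.choice(aa, size=rng.integers(3, 7)))
            got = global_align(ProteinRecord(id="1", sequence=s1),
                               ProteinRecord(id="2", sequence=s2)).score
            assert got == pytest.approx(enumerate_alignment_score(s1, s2))

    def test_deterministic(self):
        r1 = ProteinRecord(id="1", sequence="MKVLIVAADE")
        r2 = ProteinRecord(id="2", sequence="MKVIVADE")
        a = global_align(r1, r2)
        b = global_align(r1, r2)
        assert (a.aligned1, a.aligned2) == (b.aligned1, b.aligned2)


class TestIdentityMatrix:
    def test_symmetric_unit_diagonal(self):
        records, _ = make_family(4, 0.3, seed=3, spec=GrlGeneratorSpec(
            seed=3, n_tm=3, total_len_target=None))
        df = identity_matrix(records)
        assert np.allclose(df.values, df.values.T)
        assert np.allclose(np.diag(df.values), 100.0)

    def test_min_identity_of_identical_pair(self):
        recs = [ProteinRecord(id="a", sequence="MKVLIVFADE" * 4),
                ProteinRecord(id="b", sequence="MKVLIVFADE" * 4)]
        assert min_identity(recs) == 100.0

    def test_realized_divergence_recovered(self):
        records, truth = make_family(4, 0.5, seed=11)
        realized = truth.realized_identity["pairs"]
        df = identity_matrix(records)
        for (i, j), expected in realized.items():
            assert df.loc[i, j] == pytest.approx(expected, abs=10)

    def test_min_attained_on_unrelated_record(self, rng):
        records, _ = make_family(2, 0.1, seed=5, spec=GrlGeneratorSpec(
            seed=5, n_tm=3, total_len_target=None))
        noise = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=len(records[0])))
        unrelated = ProteinRecord(id="unrelated", sequence=noise)
        df = identity_matrix([*records, unrelated])
        off = df.where(~np.eye(3, dtype=bool).astype(bool))
        min_pair = off.stack().idxmin()
        assert "unrelated" in min_pair


class TestProgressiveMsa:
    def test_identical_sequences_no_gaps(self):
        recs = [ProteinRecord(id=i, sequence="MKVLIVFADE") for i in "abc"]
        msa = progressive_msa(recs)
        assert all(s == "MKVLIVFADE" for _, s in msa)

    def test_single_indel_pair(self):
        r1 = ProteinRecord(id="1", sequence="MKVLIVFADE")
        r2 = ProteinRecord(id="2", sequence="MKVLIVADE")  # F deleted
        msa = progressive_msa([r1, r2])
        gapped = dict(msa)["2"]
        assert gapped.count("-") == 1

    def test_degapping_recovers_inputs(self):
        records, _ = make_family(5, 0.3, seed=9, indel_rate=0.01,
                                 spec=GrlGeneratorSpec(seed=9, n_tm=3,
                                                       total_len_target=None))
        msa = progressive_msa(records)
        originals = {r.id: r.sequence for r in records}
        lengths = {len(s) for _, s in msa}
        assert len(lengths) == 1
        for pid, gapped in msa:
            assert gapped.replace("-", "") == originals[pid]


from tests_support import random_additive_tree, tip_distances


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4 -> terminal branches 1, 1, 3
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                            ids=["A", "B", "C"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_recovers_random_additive_trees(self, rng):
        """NJ is exact on additive metrics (topology and path lengths)."""
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true_tree, dm = random_additive_tree(rng, n)
            est = nj_tree(dm)
            true_d = tip_distances(true_tree)
            est_d = tip_distances(est)
            for pair, d in true_d.items():
                assert est_d[pair] == pytest.approx(d, abs=1e-8)

    def test_agrees_with_reference_implementation(self, rng):
        """Cross-check against scikit-bio's independent NJ on random metrics."""
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            n = int(rng.integers(4, 8))
            _, dm = random_additive_tree(rng, n)
            ours = nj_tree(dm)
            theirs = skbio_nj(dm)
            assert ours.compare_rfd(theirs) == 0

    def test_two_clade_family_separates(self):
        records, truth = make_family(6, 0.4, seed=13, topology="two_clade")
        clades = truth.realized_identity["clades"]
        dm = distance_matrix(records)
        tree = nj_tree(dm)
        clade0 = {pid for pid, c in clades.items() if c == "clade0"}
        clade1 = {pid for pid, c in clades.items() if c == "clade1"}
        splits = []
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            splits.append(tips)
        assert any(s == clade0 or s == clade1 for s in splits)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),
                    ids=["a", "b", "c"])
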