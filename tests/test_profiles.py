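"""Pseudocounted profiles, profile-profile similarity, clustering."""

import numpy as np
import pytest

from grlscreen.io import ValidationError
from grlscreen.profiles import (
    align_profiles,
    all_vs_all,
    build_profile,
    cluster,
    cluster_newick,
)
from grlscreen.synthetic_data import GrlGeneratorSpec, make_family

SMALL_SPEC = GrlGeneratorSpec(n_tm=3, total_len_target=None,
                              loop_len_in_range=(20, 40), loop_len_out_range=(10, 16))


def family_profile(seed, profile_id, n=4, divergence=0.2):
    records, _ = make_family(
        n, divergence, seed=seed, id_prefix=profile_id,
        spec=GrlGeneratorSpec(seed=seed, n_tm=SMALL_SPEC.n_tm,
                              total_len_target=None,
                              loop_len_in_range=SMALL_SPEC.loop_len_in_range,
                              loop_len_out_range=SMALL_SPEC.loop_len_out_range),
    )
    msa = [(r.id, r.sequence) for r in records]  # substitution-only: already aligned
    return build_profile(msa, profile_id=profile_id)


class TestBuildProfile:
    def test_identical_sequences_give_point_masses(self):
        prof = build_profile([("a", "AC"), ("b", "AC")], pseudocount=0.0)
        assert prof.columns[0][0] == 1.0  # A
        assert prof.columns[1][1] == 1.0  # C

    def test_even_split_column(self):
        prof = build_profile([("a", "A"), ("b", "C")], pseudocount=0.0)
        assert prof.columns[0][0] == pytest.approx(0.5)
        assert prof.columns[0][1] == pytest.approx(0.5)

    def test_pseudocount_formula(self):
        # all-A column, n=2, pseudocount 20, uniform background:
        # P(A) = (2 + 20/20) / (2 + 20) = 3/22
        prof = build_profile([("a", "A"), ("b", "A")], pseudocount=20.0)
        assert prof.columns[0][0] == pytest.approx(3 / 22)

    def test_gap_heavy_columns_dropped_and_normalized(self):
        msa = [("a", "A-C"), ("b", "A-C"), ("c", "A-C"), ("d", "AAC")]
        prof = build_profile(msa)
        assert prof.length == 2
        assert np.allclose(prof.columns.sum(axis=1), 1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            build_profile([("a", "AC"), ("b", "ACD")])

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            build_profile([("a", "AC")])


class TestAlignProfiles:
    def test_self_similarity_calibration(self):
        prof = family_profile(1, "fam")
        _, sim = align_profiles(prof, prof)
        assert sim >= 0.99

    def test_unrelated_families_low(self):
        sims = []
        for seed in range(8):
            a = family_profile(100 + seed, "a")
            b = family_profile(200 + seed, "b")
            _, sim = align_profiles(a, b)
            sims.append(sim)
        assert np.mean(sims) <= 0.05
        assert max(sims) <= 0.2

    def test_overlapping_halves_beat_cross_family(self):
        from grlscreen.synthetic_data import make_family

        records, _ = make_family(6, 0.2, seed=7, id_prefix="fam",
                                 spec=GrlGeneratorSpec(seed=7, n_tm=3, total_len_target=None))
        msa = [(r.id, r.sequence) for r in records]
        p1 = build_profile(msa[:4], profile_id="h1")
        p2 = build_profile(msa[2:], profile_id="h2")
        other = family_profile(999, "other")
        _, within = align_profiles(p1, p2)
        _, cross1 = align_profiles(p1, other)
        _, cross2 = align_profiles(p2, other)
        assert within > max(cross1, cross2)


class TestAllVsAll:
    def test_matrix_invariants(self):
        profs = [family_profile(s, f"f{s}") for s in (1, 2, 3)]
        matrix = all_vs_all(profs)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 1.0)
        assert matrix.values.min() >= 0 and matrix.values.max() <= 1

    def test_planted_pair_merges_first(self):
        records, _ = make_family(8, 0.15, seed=31, id_prefix="fam",
                                 spec=GrlGeneratorSpec(seed=31, n_tm=3, total_len_target=None))
        msa = [(r.id, r.sequence) for r in records]
        same1 = build_profile(msa[:4], profile_id="same1")
        same2 = build_profile(msa[4:], profile_id="same2")
        other = family_profile(77, "other")
        matrix = all_vs_all([same1, same2, other])
        Z = cluster(matrix)
        # first merge joins the two same-family profiles (indices 0, 1)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_identical_profiles_merge_at_zero_distance(self):
        prof = family_profile(5, "p1")
        prof2 = family_profile(5, "p2")  # same seed: identical columns
        matrix = all_vs_all([prof, prof2])
        Z = cluster(matrix)
        assert Z[0, 2] == pytest.approx(1.0 - matrix.values[0, 1], abs=1e-9)

    def test_newick_rendering_has_all_leaves(self):
        profs = [family_profile(s, f"f{s}") for s in (1, 2, 3)]
        nwk = cluster_newick(all_vs_all(profs))
        assert nwk.endswith(";")
        for p in profs:
            assert p.id in nwk


def test_within_family_similarity_exceeds_between():
    """Planted two-family separation over 20 seeded replicates."""
    within, between = [], []
    for seed in range(20):
        records_a, _ = make_family(4, 0.2, seed=1000 + seed, id_prefix="A",
                                   spec=GrlGeneratorSpec(seed=1000 + seed, n_tm=3,
                                                         total_len_target=None))
        records_b, _ = make_family(4, 0.2, seed=2000 + seed, id_prefix="B",
                                   spec=GrlGeneratorSpec(seed=2000 + seed, n_tm=3,
                                                         total_len_target=None))
        msa_a = [(r.id, r.sequence) for r in records_a]
        msa_b = [(r.id, r.sequence) for r in records_b]
        a1 = build_profile(msa_a[:2], profile_id="a1")
        a2 = build_profile(msa_a[2:], profile_id="a2")
        b1 = build_profile(msa_b[:2], profile_id="b1")
        b2 = build_profile(msa_b[2:], profile_id="b2")
        within.append(align_profiles(a1, a2)[1])
        within.append(align_profiles(b1, b2)[1])
        between.append(align_profiles(a1, b1)[1])
        between.append(align_profiles(a2, b2)[1])
    assert np.mean(within) > np.mean(between)
    assert min(within) > np.mean(between)
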