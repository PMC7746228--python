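"""Generator contracts: reproducibility, planted truth, self-validation."""

import numpy as np
import pytest

from grlscreen.io import ValidationError
from grlscreen.motif import scan_tm7
from grlscreen.screen import apply_filters
from grlscreen.synthetic_data import (
    GeneratorError,
    GrlGeneratorSpec,
    make_bundle,
    make_cohort,
    make_decoy,
    make_family,
    make_gene_model,
    make_grl_like,
)
from grlscreen.topology import predict_topology


class TestReproducibility:
    def test_bitwise_identical_under_fixed_seed(self):
        a, _ = make_grl_like(GrlGeneratorSpec(seed=123))
        b, _ = make_grl_like(GrlGeneratorSpec(seed=123))
        assert a.sequence == b.sequence

    def test_different_seeds_differ(self):
        a, _ = make_grl_like(GrlGeneratorSpec(seed=1))
        b, _ = make_grl_like(GrlGeneratorSpec(seed=2))
        assert a.sequence != b.sequence

    def test_cohort_substreams_stable_under_growth(self):
        small, _, _ = make_cohort(3, 0, seed=50)
        large, _, _ = make_cohort(5, 0, seed=50)
        for a, b in zip(small, large):
            assert a.sequence == b.sequence


class TestPositives:
    def test_zero_validation_failures_across_100_seeds(self):
        """A generated passes-all protein that fails screening is a bug."""
        for seed in range(100):
            rec, truth = make_grl_like(GrlGeneratorSpec(seed=seed))
            res = apply_filters(rec, predict_topology(rec))
            assert res.n_passed == 5, f"seed {seed}"

    def test_n_out_spec_fails_only_orientation(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=9, n_term_side="out"),
                               validate=False)
        res = apply_filters(rec, predict_topology(rec))
        assert not res.c4_n_in and res.n_passed == 4

    def test_anchor_recovery_zero_to_four(self):
        for anchors in range(5):
            rec, truth = make_grl_like(
                GrlGeneratorSpec(seed=60 + anchors, motif_anchors_conserved=anchors)
            )
            match = scan_tm7(rec, predict_topology(rec))
            assert match.anchors_matched == anchors

    def test_planted_tm_count_recovered(self):
        for n_tm in (5, 6, 7, 8):
            rec, truth = make_grl_like(
                GrlGeneratorSpec(seed=70 + n_tm, n_tm=n_tm, total_len_target=None),
            )
            assert predict_topology(rec).n_tm == n_tm
            assert len(truth.tm_intervals) == n_tm


class TestDecoys:
    @pytest.mark.parametrize(
        "kind", ["short", "long", "six_tm", "n_out", "el_gt_il", "gpcr_like"]
    )
    def test_failure_pattern_matches_kind(self, kind):
        rec, truth = make_decoy(kind, seed=5)
        res = apply_filters(rec, predict_topology(rec))
        failing = {
            name
            for name in ("c1_reciprocal", "c2_length", "c3_seven_tm",
                         "c4_n_in", "c5_il_gt_el")
            if not getattr(res, name)
        }
        assert failing == truth.expected_failures

    def test_empty_kind_list_rejected(self):
        with pytest.raises(ValidationError):
            make_decoy([])

    def test_six_tm_decoy_can_be_rescued(self):
        rec, _ = make_decoy("six_tm", seed=5)
        base = predict_topology(rec)
        rescued = predict_topology(rec, rescue_tm7=True)
        assert base.n_tm == 6
        # a six-TM decoy has no subthreshold 7th helix to find
        assert rescued.n_tm == 6


class TestFamilies:
    def test_realized_identity_matches_divergence(self):
        records, truth = make_family(4, 0.3, seed=8)
        pairs = truth.realized_identity["pairs"]
        # expected pairwise identity after two independent 30% passes
        for identity in pairs.values():
            assert 35 <= identity <= 70

    def test_two_clade_labels(self):
        records, truth = make_family(6, 0.4, seed=8, topology="two_clade")
        clades = truth.realized_identity["clades"]
        assert sorted(set(clades.values())) == ["clade0", "clade1"]


class TestGeneModels:
    def test_gene_consistent_with_record(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=14))
        gene = make_gene_model(rec, [(30, 0), (100, 1), (200, 2)])
        assert gene.protein_length == len(rec)
        assert len(gene.exons) == 4

    def test_out_of_range_intron_rejected(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=14))
        with pytest.raises(ValidationError):
            make_gene_model(rec, [(len(rec) + 5, 0)])


class TestBundles:
    def test_deterministic_under_seed(self):
        a, _ = make_bundle(seed=3, noise_sigma=1.0)
        b, _ = make_bundle(seed=3, noise_sigma=1.0)
        assert np.array_equal(a.coords, b.coords)

    def test_antiparallel_flips_alternate_helices(self):
        par, _ = make_bundle(seed=1, antiparallel=False, noise_sigma=0.0,
                             residues_per_helix=10)
        anti, _ = make_bundle(seed=1, antiparallel=True, noise_sigma=0.0,
                              residues_per_helix=10)
        # helix 0 identical, helix 1 runs in the opposite z direction
        assert np.allclose(par.coords[:10], anti.coords[:10])
        z_par = par.coords[10:20, 2]
        z_anti = anti.coords[10:20, 2]
        assert np.all(np.diff(z_par) > 0) and np.all(np.diff(z_anti) < 0)

    def test_truth_records_noise(self):
        _, truth = make_bundle(seed=2, noise_sigma=2.5)
        assert truth.noise_sigma == 2.5
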