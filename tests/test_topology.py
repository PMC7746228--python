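"""Hydropathy profiles, TM-segment calling, and orientation assignment."""

import numpy as np
import pytest

from grlscreen.io import ProteinRecord, ValidationError
from grlscreen.synthetic_data import GrlGeneratorSpec, make_grl_like
from grlscreen.topology import (
    KYTE_DOOLITTLE,
    HydropathyProfile,
    assign_orientation,
    compute_hydropathy,
    loop_length_summary,
    predict_tm_segments,
    predict_topology,
)


def brute_force_segments(values, threshold, min_len, merge_gap, max_len=30):
    """Independent re-derivation of the segment-calling contract."""
    flags = [v >= threshold for v in values]
    runs = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for start, end in merged:
        if end - start < min_len:
            continue
        if end - start > max_len:
            excess = end - start - max_len
            start += excess // 2
            end = start + max_len
        out.append((start, end))
    return out


class TestHydropathy:
    def test_poly_leucine_full_window(self):
        rec = ProteinRecord(id="L", sequence="L" * 19)
        prof = compute_hydropathy(rec, window=19)
        assert np.allclose(prof.values, KYTE_DOOLITTLE["L"])
        assert np.allclose(prof.values, 3.8)

    def test_poly_lysine_full_window(self):
        rec = ProteinRecord(id="K", sequence="K" * 19)
        prof = compute_hydropathy(rec, window=19)
        assert np.allclose(prof.values, -3.9)

    def test_all_x_is_zero(self):
        rec = ProteinRecord(id="X", sequence="X" * 25)
        assert np.allclose(compute_hydropathy(rec).values, 0.0)

    def test_edges_carry_nearest_full_window_value(self):
        rec = ProteinRecord(id="m", sequence="K" * 10 + "L" * 30 + "K" * 10)
        prof = compute_hydropathy(rec, window=19)
        assert np.allclose(prof.values[:9], prof.values[9])
        assert np.allclose(prof.values[-9:], prof.values[-10])

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            compute_hydropathy(ProteinRecord(id="s", sequence="MKV"), window=19)


class TestSegmentCalling:
    def test_seven_planted_tms_recovered(self):
        # 25-aa poly-L cores: wide enough that the 19-residue window keeps
        # an above-threshold run of >= min_len between charged loops
        seq = ("KE" * 13)[:25].join(["L" * 25] * 7)
        seq = "KE" * 5 + seq + "KE" * 5
        rec = ProteinRecord(id="seven", sequence=seq)
        prof = compute_hydropathy(rec)
        segments = predict_tm_segments(prof)
        assert segments == brute_force_segments(prof.values, 1.5, 15, 3)
        assert len(segments) == 7

    def test_poly_glutamate_has_no_segments(self):
        rec = ProteinRecord(id="E", sequence="E" * 100)
        assert predict_tm_segments(compute_hydropathy(rec)) == []

    def test_close_runs_merged(self):
        # two hydrophobic runs separated by a 2-residue dip merge at gap 3
        values = np.array([0.0] * 5 + [2.0] * 18 + [1.0] * 2 + [2.0] * 18 + [0.0] * 5)
        prof = HydropathyProfile(values=values, window=19)
        segments = predict_tm_segments(prof, 1.5, 15, 3)
        assert len(segments) == 1  # merged across the dip (then trimmed to 30)
        assert segments == brute_force_segments(values, 1.5, 15, 3)

    def test_overlong_run_trimmed_to_30(self):
        values = np.array([0.0] * 4 + [2.5] * 44 + [0.0] * 4)
        prof = HydropathyProfile(values=values, window=19)
        ((start, end),) = predict_tm_segments(prof, 1.5, 15, 3)
        assert end - start == 30

    def test_matches_oracle_on_random_profiles(self, rng):
        for _ in range(25):
            values = rng.normal(0.5, 1.5, size=rng.integers(40, 200))
            prof = HydropathyProfile(values=values, window=19)
            assert predict_tm_segments(prof, 1.5, 15, 3) == brute_force_segments(
                values, 1.5, 15, 3
            )

    def test_reversal_mirrors_segments(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=11))
        fwd = predict_tm_segments(compute_hydropathy(rec))
        rev = ProteinRecord(id="rev", sequence=rec.sequence[::-1])
        bwd = predict_tm_segments(compute_hydropathy(rev))
        n = len(rec)
        mirrored = sorted((n - e, n - s) for s, e in fwd)
        assert bwd == mirrored


class TestOrientation:
    @staticmethod
    def _record(n_side_kr: int, c_side_kr: int) -> ProteinRecord:
        n_loop = ("K" * n_side_kr + "G" * 20)[:20]
        c_loop = ("K" * c_side_kr + "G" * 20)[:20]
        return ProteinRecord(id="one_tm", sequence=n_loop + "L" * 21 + c_loop)

    def test_positive_inside_n_in(self):
        rec = self._record(8, 1)
        topo = assign_orientation(rec, [(20, 41)])
        assert topo.n_term_side == "in"

    def test_positive_inside_mirrored(self):
        rec = self._record(1, 8)
        topo = assign_orientation(rec, [(20, 41)])
        assert topo.n_term_side == "out"

    def test_tie_breaks_to_in(self):
        rec = self._record(3, 3)
        assert assign_orientation(rec, [(20, 41)]).n_term_side == "in"

    def test_zero_segments_rejected(self):
        with pytest.raises(ValidationError):
            assign_orientation(ProteinRecord(id="x", sequence="MKV"), [])

    def test_loop_sides_alternate(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=5))
        topo = predict_topology(rec)
        sides = [side for _, _, side in topo.loops]
        assert all(a != b for a, b in zip(sides, sides[1:]))
        assert topo.loops[0][2] == topo.n_term_side


class TestLoopSummary:
    def test_sums_by_side(self):
        rec, truth = make_grl_like(GrlGeneratorSpec(seed=8))
        topo = predict_topology(rec)
        il, el = loop_length_summary(topo)
        # predicted boundaries jitter around planted ones, but the balance
        # and rough magnitudes must match the generator's specification
        assert il > el
        assert abs(il - truth.il_total) < 60
        assert abs(el - truth.el_total) < 60

    def test_degenerate_all_out(self):
        from grlscreen.topology import TopologyModel

        topo = TopologyModel(
            segments=((10, 30),),
            loops=((0, 10, "out"), (30, 45, "in")),
            n_term_side="out",
        )
        il, el = loop_length_summary(topo)
        assert (il, el) == (15, 10)


class TestCuration:
    def test_planted_count_recovered_across_seeds(self):
        for seed in range(25):
            rec, _ = make_grl_like(GrlGeneratorSpec(seed=seed))
            assert predict_topology(rec).n_tm == 7

    def test_rescue_restores_subthreshold_tm7(self):
        # six strong TMs plus a mildly hydrophobic 7th (windowed mean ~1.2:
        # under the 1.5 calling threshold, over the rescue threshold 1.0)
        loop = "KD" * 8
        seq = (
            loop
            + ("L" * 24 + loop) * 6
            + "AAAT" * 9
            + "DG" * 10
        )
        weakened = ProteinRecord(id="weak7", sequence=seq)
        base = predict_topology(weakened)
        assert base.n_tm == 6
        rescued = predict_topology(weakened, rescue_tm7=True)
        assert rescued.n_tm == 7
        assert rescued.segments[-1][0] > rescued.segments[-2][1]

    def test_drop_reentrant_removes_extra_n_segment(self):
        rec, _ = make_grl_like(GrlGeneratorSpec(seed=4))
        extra = "G" * 12 + "L" * 21 + "G" * 12
        augmented = ProteinRecord(id="eight", sequence=extra + rec.sequence)
        assert predict_topology(augmented).n_tm == 8
        curated = predict_topology(augmented, drop_reentrant=True)
        assert curated.n_tm == 7
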