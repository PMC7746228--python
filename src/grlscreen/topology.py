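"""Transmembrane topology prediction from sequence alone.

A windowed Kyte–Doolittle hydropathy profile is thresholded into candidate
TM segments, and the membrane orientation (which loops are cytoplasmic) is
chosen by the positive-inside rule: of the two alternating side assignments,
the one placing more lysines and arginines on the inside wins.  This is a
deliberately simple single-sequence predictor in the spirit of classic
hydropathy-plot analysis, standing in for HMM-based topology servers; two
optional curation passes mirror the manual fixes such servers typically
need on this protein family (a spurious extra N-terminal segment from a
membrane re-entrant helix, and a subthreshold final TM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from grlscreen.io import ProteinRecord, ValidationError

# Kyte & Doolittle (1982) hydropathy values; X is treated as neutral (0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.5
DEFAULT_MIN_LEN = 15
DEFAULT_MERGE_GAP = 3
MAX_TM_LEN = 30


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-residue windowed mean hydropathy.

    ``values`` has one entry per residue; positions within half a window of
    either end carry the nearest full-window value, so the profile has no
    edge taper.
    """

    values: np.ndarray
    window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError(f"window must be odd and positive, got {self.window}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TopologyModel:
    """TM segments plus loop side labels for one protein.

    ``segments`` are 0-based half-open residue intervals labelled TM;
    ``loops`` are ``(start, end, side)`` with side in {"in", "out"},
    covering the N-tail, inter-TM loops, and C-tail; sides strictly
    alternate and ``n_term_side`` equals the side of the first loop.
    """

    segments: tuple[tuple[int, int], ...]
    loops: tuple[tuple[int, int, str], ...]
    n_term_side: str

    def __post_init__(self) -> None:
        if self.n_term_side not in ("in", "out"):
            raise ValidationError(f"n_term_side must be in/out, got {self.n_term_side}")
        prev_side = None
        for _, _, side in self.loops:
            if side not in ("in", "out"):
                raise ValidationError(f"loop side must be in/out, got {side}")
            if prev_side is not None and side == prev_side:
                raise ValidationError("loop sides must strictly alternate")
            prev_side = side
        if self.loops and self.loops[0][2] != self.n_term_side:
            raise ValidationError("n_term_side must equal the side of the first loop")
        prev_end = -1
        for start, end in self.segments:
            if start <= prev_end:
                raise ValidationError("TM segments must be disjoint and sorted")
            prev_end = end

    @property
    def n_tm(self) -> int:
        return len(self.segments)


def compute_hydropathy(record: ProteinRecord, window: int = DEFAULT_WINDOW) -> HydropathyProfile:
    """Windowed mean Kyte–Doolittle hydropathy, one value per residue."""
    seq = record.sequence
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and positive, got {window}")
    if len(seq) < window:
        raise ValidationError(
            f"{record.id}: sequence length {len(seq)} shorter than window {window}"
        )
    raw = np.array([KYTE_DOOLITTLE[a] for a in seq], dtype=float)
    kernel = np.ones(window) / window
    full = np.convolve(raw, kernel, mode="valid")  # length L - window + 1
    half = window // 2
    values = np.empty(len(seq), dtype=float)
    values[half:len(seq) - half] = full
    values[:half] = full[0]
    values[len(seq) - half:] = full[-1]
    return HydropathyProfile(values=values, window=window)


def _runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (0-based half-open) of values >= threshold."""
    above = values >= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def predict_tm_segments(
    profile: HydropathyProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    max_len: int = MAX_TM_LEN,
) -> list[tuple[int, int]]:
    """Call TM segments from a hydropathy profile.

    Maximal runs of windowed hydropathy >= ``threshold`` are merged when
    separated by <= ``merge_gap`` residues, runs shorter than ``min_len``
    are discarded, and runs longer than ``max_len`` are trimmed
    symmetrically to ``max_len``.
    """
    runs = _runs_above(profile.values, threshold)
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    segments = []
    for start, end in merged:
        if end - start < min_len:
            continue
        if end - start > max_len:
            excess = end - start - max_len
            start += excess // 2
            end = start + max_len
        segments.append((start, end))
    return segments


def _loops_for(
    seq_len: int, segments: list[tuple[int, int]], n_term_side: str
) -> tuple[tuple[int, int, str], ...]:
    """Loop intervals (tails included) with alternating sides from the N side.

    Zero-length tails/loops are kept as empty intervals so that side
    alternation and counting stay uniform.
    """
    sides = ["in", "out"] if n_term_side == "in" else ["out", "in"]
    loops: list[tuple[int, int, str]] = []
    prev_end = 0
    for i, (start, end) in enumerate(segments):
        loops.append((prev_end, start, sides[i % 2]))
        prev_end = end
    loops.append((prev_end, seq_len, sides[len(segments) % 2]))
    return tuple(loops)


def assign_orientation(
    record: ProteinRecord, segments: list[tuple[int, int]]
) -> TopologyModel:
    """Orient a segment set by the positive-inside rule.

    For both candidate orientations the K+R count over loops labelled
    "in" is summed (N- and C-terminal tails count as loops); the larger
    sum wins, ties going to an intracellular N-terminus.
    """
    if not segments:
        raise ValidationError(f"{record.id}: orientation undefined with zero TM segments")
    seq = record.sequence

    def kr_inside(n_term_side: str) -> int:
        total = 0
        for start, end, side in _loops_for(len(seq), list(segments), n_term_side):
            if side == "in":
                total += sum(1 for a in seq[start:end] if a in "KR")
        return total

    n_term_side = "in" if kr_inside("in") >= kr_inside("out") else "out"
    return TopologyModel(
        segments=tuple(segments),
        loops=_loops_for(len(seq), list(segments), n_term_side),
        n_term_side=n_term_side,
    )


def loop_length_summary(topo: TopologyModel) -> tuple[int, int]:
    """Total intracellular and extracellular loop lengths (tails included)."""
    il_total = sum(end - start for start, end, side in topo.loops if side == "in")
    el_total = sum(end - start for start, end, side in topo.loops if side == "out")
    return il_total, el_total


def predict_topology(
    record: ProteinRecord,
    *,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    drop_reentrant: bool = False,
    rescue_tm7: bool = False,
    expected_tm: int = 7,
) -> TopologyModel:
    """Full prediction: hydropathy -> segments -> optional curation -> orientation.

    ``drop_reentrant`` removes the first segment when ``expected_tm + 1``
    segments are called and the first lies within the first 60 residues
    (the re-entrant-helix artefact).  ``rescue_tm7`` re-scans C-terminal of
    the last segment at ``threshold - 0.5`` when exactly ``expected_tm - 1``
    segments are called (the subthreshold-final-TM artefact).  Both are off
    by default: they correspond to manual curation, not the base predictor.
    """
    profile = compute_hydropathy(record, window=window)
    segments = predict_tm_segments(profile, threshold, min_len, merge_gap)

    if drop_reentrant and len(segments) == expected_tm + 1 and segments[0][1] <= 60:
        segments = segments[1:]

    if rescue_tm7 and len(segments) == expected_tm - 1 and segments:
        tail_start = segments[-1][1]
        tail_values = profile.values[tail_start:]
        if len(tail_values) >= min_len:
            tail_profile = HydropathyProfile(values=tail_values, window=profile.window)
            extra = predict_tm_segments(tail_profile, threshold - 0.5, min_len, merge_gap)
            if extra:
                start, end = extra[0]
                segments = segments + [(tail_start + start, tail_start + end)]

    return assign_orientation(record, segments)
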