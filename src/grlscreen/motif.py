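"""Scanner for the diagnostic TM7 motif (T/S)Yhhhhh(Q/K/E)(F/L/M).

The motif is the only known primary-sequence signature of the GRL
superfamily: a 9-mer in the C-terminal half of the last TM domain whose
four specific positions (the "anchors" T/S, Y, Q/K/E, F/L/M) flank a
five-residue hydrophobic run.  Divergent family members keep only some
anchors, so the scanner reports a per-window anchor-conservation count
rather than a binary hit; a Y->F substitution at the second anchor can
optionally be counted as conservative, matching how divergent animal
family members are usually read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from grlscreen.io import ProteinRecord, ValidationError
from grlscreen.topology import TopologyModel

MOTIF_LENGTH = 9
# Conventional hydrophobic class, aromatics included; X never qualifies.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVWY")


@dataclass(frozen=True)
class MotifDefinition:
    """The degenerate 9-mer: 4 anchor positions around a 5-long h run."""

    anchor1: frozenset = frozenset("TS")
    anchor2: frozenset = frozenset("Y")
    anchor2_conservative: frozenset = frozenset("F")
    anchor3: frozenset = frozenset("QKE")
    anchor4: frozenset = frozenset("FLM")
    hydrophobic_class: frozenset = DEFAULT_HYDROPHOBIC

    def __post_init__(self) -> None:
        for name in ("anchor1", "anchor2", "anchor3", "anchor4"):
            if not getattr(self, name):
                raise ValidationError(f"{name} set must be non-empty")

    @property
    def anchor_sets(self) -> tuple[frozenset, ...]:
        return (self.anchor1, self.anchor2, self.anchor3, self.anchor4)

    @property
    def conservative_sets(self) -> tuple[frozenset, ...]:
        # only the Y->F substitution is named conservative by default
        return (frozenset(), self.anchor2_conservative, frozenset(), frozenset())


# Window offsets of the four anchors: positions 1, 2, 8, 9 of the 9-mer.
ANCHOR_OFFSETS = (0, 1, 7, 8)
HYDROPHOBIC_OFFSETS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class MotifMatch:
    """Best-scoring 9-mer window and its per-anchor accounting.

    ``start`` is the 0-based residue index of the window, or None for the
    no-match sentinel.  ``anchor_flags[i]`` marks a position counted toward
    ``anchors_matched``; ``conservative_flags[i]`` marks those counted only
    through the anchor's conservative set (so it implies ``anchor_flags[i]``).
    """

    start: int | None
    anchors_matched: int
    anchor_flags: tuple[bool, bool, bool, bool]
    conservative_flags: tuple[bool, bool, bool, bool]
    hydrophobic_ok: bool
    window_sequence: str

    def __post_init__(self) -> None:
        if self.anchors_matched != sum(self.anchor_flags):
            raise ValidationError("anchors_matched must equal the count of anchor_flags")
        for a, c in zip(self.anchor_flags, self.conservative_flags):
            if c and not a:
                raise ValidationError("a conservative position must be a counted anchor")

    @property
    def n_conservative(self) -> int:
        return sum(self.conservative_flags)


def score_window(
    window: str,
    definition: MotifDefinition | None = None,
    *,
    count_conservative: bool = True,
    start: int | None = None,
) -> MotifMatch:
    """Score one 9-mer against the motif.

    An anchor position counts when its residue is in the anchor set, or —
    with ``count_conservative`` — in that anchor's conservative set (the
    flag then records the substitution).  The five middle positions do not
    affect the anchor count; ``hydrophobic_ok`` records whether at least 4
    of the 5 belong to the hydrophobic class.
    """
    definition = definition or MotifDefinition()
    if len(window) != MOTIF_LENGTH:
        raise ValidationError(f"motif window must be {MOTIF_LENGTH} residues, got {len(window)}")
    anchor_flags = []
    conservative_flags = []
    for offset, anchors, conservative in zip(
        ANCHOR_OFFSETS, definition.anchor_sets, definition.conservative_sets
    ):
        residue = window[offset]
        exact = residue in anchors
        cons = (not exact) and count_conservative and residue in conservative
        anchor_flags.append(exact or cons)
        conservative_flags.append(cons)
    h_count = _h_run_count(window, definition)
    return MotifMatch(
        start=start,
        anchors_matched=sum(anchor_flags),
        anchor_flags=tuple(anchor_flags),
        conservative_flags=tuple(conservative_flags),
        hydrophobic_ok=h_count >= 4,
        window_sequence=window,
    )


def _h_run_count(window: str, definition: MotifDefinition) -> int:
    return sum(window[o] in definition.hydrophobic_class for o in HYDROPHOBIC_OFFSETS)


def no_match_sentinel() -> MotifMatch:
    return MotifMatch(
        start=None,
        anchors_matched=0,
        anchor_flags=(False,) * 4,
        conservative_flags=(False,) * 4,
        hydrophobic_ok=False,
        window_sequence="",
    )


def tm7_search_region(topo: TopologyModel, seq_len: int, margin: int = 10) -> tuple[int, int]:
    """Window-start range for the TM7 scan (0-based half-open).

    Anchored on the last predicted TM segment: starts from 5 residues
    before its midpoint through ``margin`` residues past its end, clipped
    so a full 9-mer fits in the sequence.
    """
    start, end = topo.segments[-1]
    mid = (start + end) // 2
    lo = max(0, mid - 5)
    hi = min(end + margin, seq_len - MOTIF_LENGTH) + 1
    return lo, max(lo, hi)


def scan_tm7(
    record: ProteinRecord,
    topo: TopologyModel,
    definition: MotifDefinition | None = None,
    *,
    count_conservative: bool = True,
    margin: int = 10,
) -> MotifMatch:
    """Find the best motif window in the TM7 region.

    Every 9-mer whose start lies in the TM7 search region is scored; the
    window maximising the anchor count wins, ties broken by more
    hydrophobic-run positions in class h, then by leftmost start.  If no
    full window fits the region, a no-match sentinel is returned.
    """
    definition = definition or MotifDefinition()
    if not topo.segments:
        raise ValidationError(f"{record.id}: TM7 scan needs at least one TM segment")
    lo, hi = tm7_search_region(topo, len(record), margin)
    best: MotifMatch | None = None
    best_key = None
    for start in range(lo, hi):
        window = record.sequence[start : start + MOTIF_LENGTH]
        if len(window) < MOTIF_LENGTH:
            break
        match = score_window(
            window, definition, count_conservative=count_conservative, start=start
        )
        key = (match.anchors_matched, _h_run_count(window, definition), -start)
        if best_key is None or key > best_key:
            best, best_key = match, key
    if best is None:
        return no_match_sentinel()
    return best


def motif_conservation_table(
    records: Sequence[ProteinRecord],
    topologies: dict[str, TopologyModel],
    definition: MotifDefinition | None = None,
    *,
    count_conservative: bool = True,
) -> pd.DataFrame:
    """Batch TM7 scan: one row per protein, in input order.

    Columns: protein_id, anchors_matched, n_conservative, start (1-based,
    empty for the sentinel), window.
    """
    definition = definition or MotifDefinition()
    rows = []
    for record in records:
        match = scan_tm7(
            record, topologies[record.id], definition, count_conservative=count_conservative
        )
        rows.append(
            {
                "protein_id": record.id,
                "anchors_matched": match.anchors_matched,
                "n_conservative": match.n_conservative,
                "start": None if match.start is None else match.start + 1,
                "window": match.window_sequence,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "anchors_matched", "n_conservative", "start", "window"]
    )
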