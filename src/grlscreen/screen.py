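"""The five-point retention screen for candidate GRL proteins.

A candidate is kept when it satisfies "most or all" of: (i) its best
significant homology hit is a GRL or DUF3537 family member (or it has no
significant similarity to any other family); (ii) its length falls in the
~350-500 residue band typical of the family; (iii) seven predicted TM
domains; (iv) an intracellular N-terminus; (v) total intracellular loop
length exceeding total extracellular loop length.  "Most or all" is
operationalised as a configurable minimum criterion count, >=4 of 5 by
default, and the "~" of the length band as an explicit slack parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from grlscreen.io import HitTableRow, ProteinRecord, ValidationError
from grlscreen.topology import TopologyModel, loop_length_summary

GRL_FAMILIES = frozenset({"GRL", "DUF3537"})


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the retention screen (defaults follow the study design)."""

    len_min: int = 350
    len_max: int = 500
    len_slack: int = 30
    required_tm_count: int = 7
    require_n_in: bool = True
    require_il_gt_el: bool = True
    evalue_max: float = 0.05
    coverage_min: float = 50.0
    min_criteria_passed: int = 4

    def __post_init__(self) -> None:
        if self.len_min >= self.len_max:
            raise ValidationError("len_min must be < len_max")
        if not 0 < self.coverage_min <= 100:
            raise ValidationError("coverage_min must be in (0,100]")
        if not 1 <= self.min_criteria_passed <= 5:
            raise ValidationError("min_criteria_passed must be in [1,5]")


@dataclass(frozen=True)
class ScreenResult:
    """Per-criterion booleans and the overall verdict for one candidate."""

    protein_id: str
    c1_reciprocal: bool
    c2_length: bool
    c3_seven_tm: bool
    c4_n_in: bool
    c5_il_gt_el: bool
    n_passed: int
    retained: bool

    def __post_init__(self) -> None:
        expected = sum(
            [self.c1_reciprocal, self.c2_length, self.c3_seven_tm, self.c4_n_in, self.c5_il_gt_el]
        )
        if self.n_passed != expected:
            raise ValidationError(
                f"{self.protein_id}: n_passed={self.n_passed} but {expected} criteria true"
            )

    def as_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "c1_reciprocal": self.c1_reciprocal,
            "c2_length": self.c2_length,
            "c3_seven_tm": self.c3_seven_tm,
            "c4_n_in": self.c4_n_in,
            "c5_il_gt_el": self.c5_il_gt_el,
            "n_passed": self.n_passed,
            "retained": self.retained,
        }


def check_reciprocal(
    hits: Sequence[HitTableRow], query_id: str, criteria: FilterCriteria | None = None
) -> bool:
    """Criterion (i): the top qualifying hit is a family member, or nothing is.

    Among hits for ``query_id`` with E-value <= ``evalue_max`` and coverage
    >= ``coverage_min``, the minimum-E-value row must belong to the GRL or
    DUF3537 family — or no qualifying row may belong to any *other* family
    (the "no significant similarity to other protein families" clause,
    which also covers an empty hit list).
    """
    criteria = criteria or FilterCriteria()
    qualifying = [
        h
        for h in hits
        if h.query_id == query_id
        and h.evalue <= criteria.evalue_max
        and h.query_coverage >= criteria.coverage_min
    ]
    if not qualifying:
        return True
    top = min(qualifying, key=lambda h: h.evalue)
    if top.subject_family in GRL_FAMILIES:
        return True
    return not any(h.subject_family == "other" for h in qualifying)


def check_length(record: ProteinRecord, criteria: FilterCriteria | None = None) -> bool:
    """Criterion (ii): sequence length within the slack-widened 350-500 band."""
    criteria = criteria or FilterCriteria()
    return (
        criteria.len_min - criteria.len_slack
        <= len(record)
        <= criteria.len_max + criteria.len_slack
    )


def apply_filters(
    record: ProteinRecord,
    topo: TopologyModel,
    hits: Sequence[HitTableRow] = (),
    criteria: FilterCriteria | None = None,
) -> ScreenResult:
    """Evaluate all five criteria for one candidate and decide retention."""
    criteria = criteria or FilterCriteria()
    il_total, el_total = loop_length_summary(topo)
    c1 = check_reciprocal(hits, record.id, criteria)
    c2 = check_length(record, criteria)
    c3 = topo.n_tm == criteria.required_tm_count
    c4 = (topo.n_term_side == "in") if criteria.require_n_in else True
    c5 = (il_total > el_total) if criteria.require_il_gt_el else True
    n_passed = sum([c1, c2, c3, c4, c5])
    return ScreenResult(
        protein_id=record.id,
        c1_reciprocal=c1,
        c2_length=c2,
        c3_seven_tm=c3,
        c4_n_in=c4,
        c5_il_gt_el=c5,
        n_passed=n_passed,
        retained=n_passed >= criteria.min_criteria_passed,
    )


def screen_collection(
    records: Sequence[ProteinRecord],
    topologies: dict[str, TopologyModel],
    hit_table: Sequence[HitTableRow] = (),
    criteria: FilterCriteria | None = None,
) -> list[ScreenResult]:
    """Screen a whole collection, preserving input order.

    ``topologies`` maps protein id -> TopologyModel; every record must have
    one.
    """
    criteria = criteria or FilterCriteria()
    missing = [r.id for r in records if r.id not in topologies]
    if missing:
        raise ValidationError(f"no topology for records: {missing}")
    return [
        apply_filters(r, topologies[r.id], hit_table, criteria) for r in records
    ]


def screen_summary(
    records: Sequence[ProteinRecord], results: Sequence[ScreenResult]
) -> dict:
    """Counts per kingdom and a per-criterion failure histogram."""
    kingdom_of = {r.id: r.kingdom for r in records}
    retained_by_kingdom: dict[str, int] = {}
    failures = {k: 0 for k in ("c1_reciprocal", "c2_length", "c3_seven_tm", "c4_n_in", "c5_il_gt_el")}
    for res in results:
        if res.retained:
            kingdom = kingdom_of.get(res.protein_id) or "unknown"
            retained_by_kingdom[kingdom] = retained_by_kingdom.get(kingdom, 0) + 1
        for crit in failures:
            if not getattr(res, crit):
                failures[crit] += 1
    return {
        "n_screened": len(results),
        "n_retained": sum(r.retained for r in results),
        "retained_by_kingdom": retained_by_kingdom,
        "criterion_failures": failures,
    }
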