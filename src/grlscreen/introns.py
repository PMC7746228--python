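"""Intron positions in protein coordinates and their projection onto MSAs.

Animal genes of this receptor superfamily carry characteristic introns
near the 3' end; testing whether candidate genes share intron positions
requires (a) converting exon junctions of a gene model into codon
coordinates and phases and (b) projecting those codon positions through a
multiple alignment so positions are comparable between proteins.  An
intron's phase is its offset within the codon it interrupts (0 = between
codons); phase-0 introns are recorded at the boundary after the last
complete codon, others at the codon they split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from grlscreen.io import GeneModel, ValidationError


@dataclass(frozen=True)
class IntronMark:
    """One intron in protein coordinates.

    ``residue_index`` is 1-based: the codon containing the intron for
    phase 1/2, or the last complete codon before it for phase 0.
    """

    protein_id: str
    residue_index: int
    phase: int
    alignment_column: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValidationError(f"phase must be 0/1/2, got {self.phase}")
        if self.residue_index < 1:
            raise ValidationError("residue_index must be >= 1")


def intron_marks(gene: GeneModel) -> list[IntronMark]:
    """Derive intron marks from the exon junctions of a gene model.

    At each junction between consecutive exons the cumulative CDS length c
    gives phase = c mod 3 and residue_index = c // 3 for phase 0 (the
    boundary after that residue) or c // 3 + 1 otherwise.  Single-exon
    genes have no introns.
    """
    marks = []
    c = 0
    for start, end in gene.exons[:-1]:
        c += end - start
        phase = c % 3
        residue = c // 3 if phase == 0 else c // 3 + 1
        marks.append(IntronMark(protein_id=gene.protein_id, residue_index=residue, phase=phase))
    return marks


def _residue_to_column(gapped: str, residue_index: int) -> int:
    """1-based alignment column of the residue_index-th residue."""
    seen = 0
    for col, ch in enumerate(gapped, start=1):
        if ch not in "-.":
            seen += 1
            if seen == residue_index:
                return col
    raise ValidationError(
        f"residue index {residue_index} beyond degapped length {seen}"
    )


def project_to_alignment(
    marks: Sequence[IntronMark], msa: Sequence[tuple[str, str]]
) -> list[IntronMark]:
    """Attach alignment columns to intron marks.

    ``msa`` is (id, gapped sequence) pairs; every mark's protein must be
    present.  Projection is monotone in residue index.
    """
    rows = dict(msa)
    out = []
    for mark in marks:
        if mark.protein_id not in rows:
            raise ValidationError(f"{mark.protein_id} absent from alignment")
        col = _residue_to_column(rows[mark.protein_id], mark.residue_index)
        out.append(replace(mark, alignment_column=col))
    return out


def conservation_groups(
    marks: Sequence[IntronMark],
    grouping: dict[str, str] | None = None,
    tolerance: int = 0,
) -> pd.DataFrame:
    """Group projected intron marks by shared alignment position and phase.

    Marks are shared when their phases are equal and their alignment
    columns differ by at most ``tolerance``; groups are built greedily in
    column order.  ``grouping`` maps protein id to a label (e.g. kingdom);
    the report lists, per group, its column range, phase, member proteins,
    labels, and whether it spans more than one label.  Marks without an
    alignment column are rejected; an empty mark list yields an empty
    report.
    """
    for mark in marks:
        if mark.alignment_column is None:
            raise ValidationError("marks must be projected before grouping")
    grouping = grouping or {}
    ordered = sorted(marks, key=lambda m: (m.phase, m.alignment_column, m.protein_id))
    groups: list[list[IntronMark]] = []
    for mark in ordered:
        if (
            groups
            and groups[-1][0].phase == mark.phase
            and mark.alignment_column - groups[-1][-1].alignment_column <= tolerance
        ):
            groups[-1].append(mark)
        else:
            groups.append([mark])
    rows = []
    for gid, members in enumerate(groups):
        labels = sorted({grouping.get(m.protein_id, "unknown") for m in members})
        rows.append(
            {
                "group": gid,
                "phase": members[0].phase,
                "column_min": members[0].alignment_column,
                "column_max": members[-1].alignment_column,
                "n_members": len(members),
                "proteins": ",".join(sorted(m.protein_id for m in members)),
                "labels": ",".join(labels),
                "cross_label": len(labels) > 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "phase", "column_min", "column_max",
            "n_members", "proteins", "labels", "cross_label",
        ],
    )
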