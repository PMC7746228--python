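"""Readers and writers for the external representations the pipeline touches.

Internal coordinates are 0-based half-open everywhere; user-facing formats
(GFF-like exon tables, TSV reports) are 1-based closed.  FASTA and PDB go
through Biopython; tabular formats through pandas; trees are scikit-bio
``TreeNode`` objects written as newick.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")
KINGDOMS = frozenset({"Fungi", "Protista", "Plantae", "Animalia"})
HIT_FAMILIES = frozenset({"GRL", "DUF3537", "other", "none"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, sequence, and optional inventory metadata."""

    id: str
    sequence: str
    species: str | None = None
    kingdom: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            raise ValidationError(
                f"{self.id}: disallowed letters {sorted(bad)} "
                "(20 standard amino acids plus X permitted)"
            )
        if self.kingdom is not None and self.kingdom not in KINGDOMS:
            raise ValidationError(f"{self.id}: unknown kingdom {self.kingdom!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitTableRow:
    """One homology-search hit: query, subject, E-value, coverage, family."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    subject_family: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"evalue must be >= 0, got {self.evalue}")
        if not 0 <= self.query_coverage <= 100:
            raise ValidationError(
                f"query_coverage must be in [0,100], got {self.query_coverage}"
            )
        if self.subject_family is not None and self.subject_family not in HIT_FAMILIES:
            raise ValidationError(f"unknown subject_family {self.subject_family!r}")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one protein-coding gene.

    ``exons`` are 0-based half-open intervals on the gene's nucleotide axis
    (introns are the gaps between them), sorted in CDS orientation;
    minus-strand inputs are normalised at parse time.
    """

    gene_id: str
    protein_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(f"{self.gene_id}: empty exon ({start},{end})")
            if start <= prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass(frozen=True)
class CoordinateSet:
    """Ordered C-alpha coordinates for one structure (angstroms)."""

    id: str
    residue_indices: tuple[int, ...]
    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"{self.id}: coords must be (n, 3)")
        if len(self.residue_indices) != coords.shape[0]:
            raise ValidationError(f"{self.id}: index/coordinate length mismatch")
        idx = np.asarray(self.residue_indices)
        if len(idx) < 3:
            raise ValidationError(f"{self.id}: at least 3 residues required")
        if np.any(np.diff(idx) <= 0) or np.any(idx < 1):
            raise ValidationError(f"{self.id}: residue indices must be strictly increasing positives")

    def __len__(self) -> int:
        return len(self.residue_indices)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Sequences are uppercased; letters outside the 20 standard amino acids
    plus X are rejected, as are duplicate identifiers and empty files.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, *, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seq_records)


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps allowed) as (id, gapped sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise FormatError(f"no records in {path}")
    lengths = {len(s) for _, s in out}
    if len(lengths) != 1:
        raise FormatError(f"aligned FASTA {path} has unequal row lengths {sorted(lengths)}")
    return out


# ---------------------------------------------------------------------------
# Hit tables

_HIT_COLUMNS = ["query_id", "subject_id", "evalue", "query_coverage"]


def read_hit_table(path: str | Path) -> list[HitTableRow]:
    """Read a TSV homology-hit table.

    Required columns: query_id, subject_id, evalue, query_coverage; an
    optional subject_family column annotates the subject's protein family.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty hit table {path}") from exc
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    rows = []
    for _, r in df.iterrows():
        try:
            evalue = float(r["evalue"])
            coverage = float(r["query_coverage"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed numeric field in row {r.to_dict()}") from exc
        family = r.get("subject_family")
        if pd.isna(family):
            family = None
        rows.append(
            HitTableRow(
                query_id=r["query_id"],
                subject_id=r["subject_id"],
                evalue=evalue,
                query_coverage=coverage,
                subject_family=family,
            )
        )
    return rows


def write_hit_table(rows: Iterable[HitTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "subject_id": r.subject_id,
                "evalue": r.evalue,
                "query_coverage": r.query_coverage,
                "subject_family": r.subject_family,
            }
            for r in rows
        ],
        columns=_HIT_COLUMNS + ["subject_family"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (exon-table TSV, 1-based closed intervals externally)

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model exon table.

    TSV columns: gene_id, protein_id, exon_start, exon_end, strand — one row
    per exon, 1-based closed intervals (GFF convention), converted here to
    0-based half-open.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty gene-model table {path}") from exc
    required = ["gene_id", "protein_id", "exon_start", "exon_end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    models = []
    for (gene_id, protein_id, strand), grp in df.groupby(
        ["gene_id", "protein_id", "strand"], sort=False
    ):
        exons = [
            (int(s) - 1, int(e))  # 1-based closed -> 0-based half-open
            for s, e in zip(grp["exon_start"], grp["exon_end"])
        ]
        exons.sort()
        if strand == "-":
            # normalise to CDS orientation: mirror on the gene axis
            span = max(e for _, e in exons)
            exons = sorted((span - e, span - s) for s, e in exons)
        models.append(
            GeneModel(gene_id=gene_id, protein_id=protein_id, exons=tuple(exons), strand=strand)
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for m in models:
        for start, end in m.exons:
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "protein_id": m.protein_id,
                    "exon_start": start + 1,
                    "exon_end": end,
                    "strand": m.strand,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PDB coordinates

def read_coordinates(path: str | Path, *, structure_id: str | None = None) -> CoordinateSet:
    """Read C-alpha coordinates from a PDB file.

    Only ATOM records of the first chain are used; for altlocs the first
    occurrence per residue wins.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    sid = structure_id or Path(path).stem
    structure = parser.get_structure(sid, str(path))
    indices: list[int] = []
    coords: list[np.ndarray] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    indices.append(residue.id[1])
                    coords.append(residue["CA"].get_coord())
            break  # first chain only
        break  # first model only
    if not coords:
        raise FormatError(f"no C-alpha atoms in {path}")
    return CoordinateSet(id=sid, residue_indices=tuple(indices), coords=np.array(coords, float))


def write_coordinates(cs: CoordinateSet, path: str | Path) -> None:
    """Write a CoordinateSet as a minimal CA-only PDB file."""
    with open(path, "w") as fh:
        for serial, (ri, (x, y, z)) in enumerate(zip(cs.residue_indices, cs.coords), start=1):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA A{ri:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trees and reports

def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio ``TreeNode`` as newick with branch lengths."""
    leaves = list(tree.tips())
    if len(leaves) < 2:
        raise ValidationError("refusing to write a tree with fewer than 2 leaves")
    tree.write(str(path), format="newick")


def write_report(results: Sequence, path: str | Path) -> None:
    """Write one screening result per TSV row (see :mod:`grlscreen.screen`)."""
    rows = [r.as_dict() for r in results]
    cols = list(rows[0].keys()) if rows else [
        "protein_id", "c1_reciprocal", "c2_length", "c3_seven_tm",
        "c4_n_in", "c5_il_gt_el", "n_passed", "retained",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged inventory fixture

def load_table1(*, with_sequences: bool = False, seed: int = 20201204) -> list[ProteinRecord]:
    """Load the packaged 17-candidate inventory (species, kingdom, accession).

    The packaged file carries metadata only, transcribed from the published
    inventory of candidate GRLs in unicellular eukaryotes; the real protein
    sequences live in the study's supplementary material and are not
    redistributed here.  With ``with_sequences=True`` each record is given a
    deterministic synthetic GRL-like sequence (clearly a stand-in) so the
    inventory can flow through sequence-consuming stages in examples/tests.
    """
    ref = importlib.resources.files("grlscreen.data") / "table1_candidates.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    records = []
    for i, row in df.iterrows():
        if with_sequences:
            from grlscreen.synthetic_data import GrlGeneratorSpec, make_grl_like

            rec, _ = make_grl_like(GrlGeneratorSpec(seed=seed + i), protein_id=row["protein"])
            sequence = rec.sequence
        else:
            sequence = "X"  # metadata-only placeholder
        records.append(
            ProteinRecord(
                id=row["protein"],
                sequence=sequence,
                species=row["species"],
                kingdom=row["kingdom"],
                accession=row["accession"],
            )
        )
    return records


def table1_summary(records: Sequence[ProteinRecord]) -> dict:
    """Per-kingdom / per-species tallies of an inventory collection."""
    by_kingdom: dict[str, int] = {}
    by_species: dict[str, int] = {}
    for r in records:
        if r.kingdom:
            by_kingdom[r.kingdom] = by_kingdom.get(r.kingdom, 0) + 1
        if r.species:
            by_species[r.species] = by_species.get(r.species, 0) + 1
    return {
        "n_candidates": len(records),
        "by_kingdom": by_kingdom,
        "by_species": by_species,
        "n_fungal_species": len(
            {r.species for r in records if r.kingdom == "Fungi" and r.species}
        ),
    }
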