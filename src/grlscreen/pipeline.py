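"""Orchestration of the full screening analysis from one JSON configuration.

Stages run in a fixed order — topology, screen, motif, profile matrix,
identity/tree, introns, structures — each writing its TSV artifact into
the output directory, followed by a consolidated ``summary.json`` whose
numbers are recomputed from the stage files (a consistency check, not a
second code path).  The run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from grlscreen import alignment_phylo, introns, io, motif, profiles, screen, structcompare, topology
from grlscreen.io import FormatError, ValidationError

log = logging.getLogger("grlscreen")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    fasta: str
    out_dir: str
    hit_table: str | None = None
    gene_models: str | None = None
    msa: str | None = None
    structures: list[str] = field(default_factory=list)
    structure_metadata: dict = field(default_factory=dict)
    criteria: screen.FilterCriteria = field(default_factory=screen.FilterCriteria)
    seed: int = 0
    min_msa_sequences: int = 15
    min_estimated_tm: float = 0.17
    topology_kwargs: dict = field(default_factory=dict)
    count_conservative: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        crit = raw.pop("criteria", None)
        config = cls(**raw)
        if crit:
            config.criteria = screen.FilterCriteria(**crit)
        return config

    def validate_paths(self) -> None:
        for p in [self.fasta, self.hit_table, self.gene_models, self.msa, *self.structures]:
            if p is not None and not Path(p).exists():
                raise FormatError(f"configured input does not exist: {p}")


def run_screening_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and return the consolidated summary.

    A stage failure aborts the run with the stage name attached.  The
    summary is also written to ``<out_dir>/summary.json``.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "criteria": asdict(config.criteria)}
    stage = "setup"
    try:
        stage = "read"
        records = io.read_fasta(config.fasta)
        log.info("read %d records from %s", len(records), config.fasta)

        stage = "topology"
        topologies = {
            r.id: topology.predict_topology(r, **config.topology_kwargs) for r in records
        }
        topo_rows = []
        for r in records:
            t = topologies[r.id]
            il, el = topology.loop_length_summary(t)
            topo_rows.append(
                {
                    "protein_id": r.id,
                    "n_tm": t.n_tm,
                    "n_term_side": t.n_term_side,
                    "il_total": il,
                    "el_total": el,
                    "segments": ";".join(f"{s + 1}-{e}" for s, e in t.segments),
                }
            )
        pd.DataFrame(topo_rows).to_csv(out / "topology.tsv", sep="\t", index=False)

        stage = "screen"
        hits = io.read_hit_table(config.hit_table) if config.hit_table else []
        results = screen.screen_collection(records, topologies, hits, config.criteria)
        io.write_report(results, out / "screen.tsv")
        summary["screen"] = screen.screen_summary(records, results)

        stage = "motif"
        table = motif.motif_conservation_table(
            records, topologies, count_conservative=config.count_conservative
        )
        table.to_csv(out / "motif.tsv", sep="\t", index=False)
        summary["motif"] = {
            "max_anchors_matched": int(table["anchors_matched"].max()) if len(table) else 0,
            "mean_anchors_matched": float(table["anchors_matched"].mean()) if len(table) else 0.0,
        }

        stage = "identity_tree"
        if len(records) >= 2:
            ident = alignment_phylo.identity_matrix(records)
            ident.to_csv(out / "identity.tsv", sep="\t")
            summary["identity"] = {
                "min_identity_pct": float(
                    ident.values[~np.eye(len(ident), dtype=bool)].min()
                )
            }
            if len(records) >= 3:
                dm = alignment_phylo.distance_matrix(records)
                tree = alignment_phylo.nj_tree(dm)
                io.write_newick(tree, out / "tree.nwk")

        stage = "profiles"
        if config.msa:
            msa = io.read_aligned_fasta(config.msa)
            if len(msa) >= 4:
                half = len(msa) // 2
                prof_a = profiles.build_profile(msa[:half], profile_id="partition_a")
                prof_b = profiles.build_profile(msa[half:], profile_id="partition_b")
                matrix = profiles.all_vs_all([prof_a, prof_b])
                pd.DataFrame(
                    matrix.values, index=matrix.ids, columns=matrix.ids
                ).to_csv(out / "profile_similarity.tsv", sep="\t")

        stage = "introns"
        if config.gene_models and config.msa:
            genes = io.read_gene_models(config.gene_models)
            marks = [m for g in genes for m in introns.intron_marks(g)]
            aligned = io.read_aligned_fasta(config.msa)
            projected = introns.project_to_alignment(marks, aligned)
            report = introns.conservation_groups(projected)
            report.to_csv(out / "introns.tsv", sep="\t", index=False)
            summary["introns"] = {
                "n_introns": len(projected),
                "n_position_groups": int(len(report)),
            }

        stage = "structures"
        if config.structures:
            sets = [io.read_coordinates(p) for p in config.structures]
            admitted = [
                cs
                for cs in sets
                if structcompare.intake_filter(
                    config.structure_metadata.get(cs.id, {}),
                    min_msa_sequences=config.min_msa_sequences,
                    min_estimated_tm=config.min_estimated_tm,
                )
            ]
            summary["structures"] = {
                "n_supplied": len(sets),
                "n_admitted": len(admitted),
            }
            if len(admitted) >= 2:
                tm, rmsd = structcompare.pairwise_structure_matrix(admitted)
                tm.to_csv(out / "tm_score.tsv", sep="\t")
                rmsd.to_csv(out / "rmsd.tsv", sep="\t")

        stage = "consistency"
        _check_consistency(out, summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _check_consistency(out: Path, summary: dict) -> None:
    """Every summary number must be recoverable from a stage file."""
    screen_df = pd.read_csv(out / "screen.tsv", sep="\t")
    if int(screen_df["retained"].sum()) != summary["screen"]["n_retained"]:
        raise ValidationError("summary retained count drifted from screen.tsv")
    motif_df = pd.read_csv(out / "motif.tsv", sep="\t")
    if len(motif_df) and int(motif_df["anchors_matched"].max()) != summary["motif"][
        "max_anchors_matched"
    ]:
        raise ValidationError("summary motif maximum drifted from motif.tsv")
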