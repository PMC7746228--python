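"""Seeded generators for every input class the screening pipeline consumes.

Each generator plants known ground truth (TM architecture, loop sides,
motif anchors, intron positions, family divergence, bundle noise) and
self-validates it against the consuming module before returning, so a
generated "passes-all" protein that fails the screen is a generator bug,
not a test tolerance.  A single integer seed drives hierarchical RNG
substreams (one per protein), so enlarging a cohort does not perturb the
proteins already in it.

Composition rules make the planted truth decisive at noise 0:

* TM stretches are strongly hydrophobic (L/I/V/F; the last TM uses I/V
  outside the planted motif window so no spurious motif anchors occur in
  the scanned region);
* intracellular loops carry K and R (positive-inside rule), extracellular
  loops carry R only and 4x less of it, and loops avoid every motif-anchor
  residue so the TM7 scan region stays clean;
* extracellular loops are at least 10 residues so that a 19-residue
  hydropathy window resolves adjacent TMs as separate segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from grlscreen.io import CoordinateSet, GeneModel, ProteinRecord, ValidationError
from grlscreen.motif import MotifDefinition, scan_tm7
from grlscreen.screen import FilterCriteria, apply_filters
from grlscreen.topology import TopologyModel, loop_length_summary, predict_topology

TM_ALPHABET = "LIV"
TM_WEIGHTS = (0.40, 0.35, 0.25)
TM7_ALPHABET = "IV"  # anchor-free so the scan region carries only planted anchors
LOOP_IN_ALPHABET = "DNGP"  # plus K/R at kr_in
LOOP_OUT_ALPHABET = "DNGP"  # plus R only at kr_out
MOTIF_RUN_ALPHABET = "IVA"
NONCONSERVED_ANCHOR_ALPHABET = "IV"
CONSERVED_ANCHORS = ("T", "Y", "Q", "F")

DECOY_KINDS = ("short", "long", "six_tm", "n_out", "el_gt_il", "gpcr_like")


class GeneratorError(RuntimeError):
    """Planted truth failed self-validation against the consuming module."""


@dataclass(frozen=True)
class GrlGeneratorSpec:
    """Architecture of one synthetic GRL-like protein."""

    n_tm: int = 7
    tm_len_range: tuple[int, int] = (23, 26)
    loop_len_in_range: tuple[int, int] = (20, 80)
    loop_len_out_range: tuple[int, int] = (10, 20)
    total_len_target: tuple[int, int] | None = (350, 500)
    motif_anchors_conserved: int = 4
    anchor_pattern: tuple[str, str, str, str] | None = None
    motif_in_tm7: bool = True
    motif_tm_index: int | None = None  # 1-based TM carrying the motif; None = last
    n_term_side: str = "in"
    kr_in: float = 0.35
    kr_out: float = 0.0875
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tm < 1:
            raise ValidationError("n_tm must be >= 1")
        for name in ("tm_len_range", "loop_len_in_range", "loop_len_out_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must be a positive (lo, hi) range")
        if not 0 <= self.motif_anchors_conserved <= 4:
            raise ValidationError("motif_anchors_conserved must be in 0..4")
        if self.n_term_side not in ("in", "out"):
            raise ValidationError("n_term_side must be 'in' or 'out'")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded alongside generated data."""

    tm_intervals: tuple[tuple[int, int], ...] = ()
    loop_sides: tuple[str, ...] = ()
    n_term_side: str | None = None
    il_total: int | None = None
    el_total: int | None = None
    motif_start: int | None = None
    anchors_conserved: int | None = None
    expected_failures: frozenset = frozenset()
    realized_identity: dict | None = None
    intron_positions: tuple[tuple[int, int], ...] = ()
    noise_sigma: float | None = None


def _loop_sides(n_tm: int, n_term_side: str) -> list[str]:
    sides = []
    current = n_term_side
    for _ in range(n_tm + 1):
        sides.append(current)
        current = "out" if current == "in" else "in"
    return sides


def _sample_loop(rng: np.random.Generator, length: int, side: str,
                 kr_in: float, kr_out: float) -> str:
    if side == "in":
        kr_rate, kr_letters, alphabet = kr_in, "KR", LOOP_IN_ALPHABET
    else:
        kr_rate, kr_letters, alphabet = kr_out, "R", LOOP_OUT_ALPHABET
    out = []
    for _ in range(length):
        if rng.random() < kr_rate:
            out.append(kr_letters[rng.integers(len(kr_letters))])
        else:
            out.append(alphabet[rng.integers(len(alphabet))])
    return "".join(out)


def _sample_tm(rng: np.random.Generator, length: int, *, tm7: bool) -> str:
    if tm7:
        return "".join(TM7_ALPHABET[rng.integers(2)] for _ in range(length))
    idx = rng.choice(len(TM_ALPHABET), size=length, p=TM_WEIGHTS)
    return "".join(TM_ALPHABET[i] for i in idx)


def _motif_window(rng: np.random.Generator, spec: GrlGeneratorSpec) -> str:
    if spec.anchor_pattern is not None:
        anchors = spec.anchor_pattern
    else:
        anchors = tuple(
            CONSERVED_ANCHORS[i]
            if i < spec.motif_anchors_conserved
            else NONCONSERVED_ANCHOR_ALPHABET[rng.integers(2)]
            for i in range(4)
        )
    run = "".join(MOTIF_RUN_ALPHABET[rng.integers(len(MOTIF_RUN_ALPHABET))] for _ in range(5))
    return anchors[0] + anchors[1] + run + anchors[2] + anchors[3]


def _adjust_lengths(
    loop_lengths: list[int], sides: list[str], tm_total: int,
    target: tuple[int, int] | None,
) -> list[int]:
    """Nudge inside-loop lengths so the total hits the target band."""
    if target is None:
        return loop_lengths
    lo, hi = target
    lengths = list(loop_lengths)
    in_idx = [i for i, s in enumerate(sides) if s == "in"]
    if not in_idx:
        in_idx = list(range(len(lengths)))
    for _ in range(1000):
        total = tm_total + sum(lengths)
        if lo <= total <= hi:
            return lengths
        if total < lo:
            i = min(in_idx, key=lambda k: lengths[k])
            lengths[i] += min(lo - total, 40)
        else:
            i = max(in_idx, key=lambda k: lengths[k])
            if lengths[i] <= 20:
                raise GeneratorError(
                    f"cannot fit total length into {target} (stuck at {total})"
                )
            lengths[i] -= min(total - hi, lengths[i] - 20)
    raise GeneratorError(f"length adjustment did not converge to {target}")


def _assemble(spec: GrlGeneratorSpec, rng: np.random.Generator) -> tuple[str, PlantedTruth]:
    sides = _loop_sides(spec.n_tm, spec.n_term_side)
    tm_lens = [int(rng.integers(spec.tm_len_range[0], spec.tm_len_range[1] + 1))
               for _ in range(spec.n_tm)]
    motif_tm_1b = spec.motif_tm_index if spec.motif_tm_index is not None else spec.n_tm
    if spec.motif_in_tm7:
        # the motif's polar anchors dilute the hydropathy signal; a longer
        # TM keeps the above-threshold run comfortably over min_len
        tm_lens[motif_tm_1b - 1] = int(rng.integers(26, 29))
    loop_lens = []
    for side in sides:
        lo, hi = spec.loop_len_in_range if side == "in" else spec.loop_len_out_range
        loop_lens.append(int(rng.integers(lo, hi + 1)))
    loop_lens = _adjust_lengths(loop_lens, sides, sum(tm_lens), spec.total_len_target)

    motif_tm = motif_tm_1b
    parts: list[str] = []
    tm_intervals: list[tuple[int, int]] = []
    pos = 0
    motif_start: int | None = None
    for k in range(spec.n_tm):
        loop_seq = _sample_loop(rng, loop_lens[k], sides[k], spec.kr_in, spec.kr_out)
        parts.append(loop_seq)
        pos += len(loop_seq)
        is_motif_tm = spec.motif_in_tm7 and (k + 1 == motif_tm)
        tm_seq = _sample_tm(rng, tm_lens[k], tm7=(k + 1 == spec.n_tm))
        if is_motif_tm:
            window = _motif_window(rng, spec)
            tm_seq = tm_seq[: tm_lens[k] - 9] + window
            motif_start = pos + tm_lens[k] - 9
        parts.append(tm_seq)
        tm_intervals.append((pos, pos + tm_lens[k]))
        pos += tm_lens[k]
    parts.append(_sample_loop(rng, loop_lens[-1], sides[-1], spec.kr_in, spec.kr_out))
    sequence = "".join(parts)

    il_total = sum(l for l, s in zip(loop_lens, sides) if s == "in")
    el_total = sum(l for l, s in zip(loop_lens, sides) if s == "out")
    truth = PlantedTruth(
        tm_intervals=tuple(tm_intervals),
        loop_sides=tuple(sides),
        n_term_side=spec.n_term_side,
        il_total=il_total,
        el_total=el_total,
        motif_start=motif_start,
        anchors_conserved=spec.motif_anchors_conserved if spec.motif_in_tm7 else None,
    )
    return sequence, truth


def _validate_positive(record: ProteinRecord, spec: GrlGeneratorSpec, truth: PlantedTruth) -> None:
    topo = predict_topology(record)
    if topo.n_tm != spec.n_tm:
        raise GeneratorError(
            f"{record.id}: predicted {topo.n_tm} TMs, planted {spec.n_tm}"
        )
    if topo.n_term_side != spec.n_term_side:
        raise GeneratorError(f"{record.id}: predicted N-side {topo.n_term_side}")
    il, el = loop_length_summary(topo)
    if (il > el) != (truth.il_total > truth.el_total):
        raise GeneratorError(f"{record.id}: loop-balance mismatch (il={il}, el={el})")
    if spec.motif_in_tm7 and (spec.motif_tm_index in (None, spec.n_tm)):
        match = scan_tm7(record, topo)
        expected = truth.anchors_conserved
        if spec.anchor_pattern is None and match.anchors_matched != expected:
            raise GeneratorError(
                f"{record.id}: motif scan found {match.anchors_matched}, planted {expected}"
            )


def make_grl_like(
    spec: GrlGeneratorSpec | None = None,
    *,
    protein_id: str = "synthetic_grl",
    rng: np.random.Generator | None = None,
    validate: bool = True,
) -> tuple[ProteinRecord, PlantedTruth]:
    """Generate one GRL-like protein with planted architecture and motif.

    Deterministic under ``spec.seed``; by default the result is
    self-validated against the topology and motif modules.
    """
    spec = spec or GrlGeneratorSpec()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sequence, truth = _assemble(spec, rng)
    record = ProteinRecord(id=protein_id, sequence=sequence)
    if validate:
        _validate_positive(record, spec, truth)
    return record, truth


_DECOY_TWEAKS = {
    "short": dict(total_len_target=None,
                  loop_len_in_range=(13, 16), loop_len_out_range=(10, 12)),
    "long": dict(total_len_target=None,
                 loop_len_in_range=(80, 100), loop_len_out_range=(12, 18)),
    "six_tm": dict(n_tm=6),
    "n_out": dict(n_term_side="out"),
    "el_gt_il": dict(loop_len_in_range=(10, 14), loop_len_out_range=(40, 70),
                     kr_out=0.02),
}

_DECOY_FAILURES = {
    "short": {"c2_length"},
    "long": {"c2_length"},
    "six_tm": {"c3_seven_tm"},
    "n_out": {"c4_n_in"},
    "el_gt_il": {"c5_il_gt_el"},
    "gpcr_like": {"c4_n_in", "c5_il_gt_el"},
}


def make_decoy(
    kinds: str | Sequence[str],
    *,
    seed: int = 0,
    protein_id: str = "synthetic_decoy",
    criteria: FilterCriteria | None = None,
) -> tuple[ProteinRecord, PlantedTruth]:
    """Generate a decoy violating exactly the named screen criteria.

    ``kinds`` is one kind or a combination from: short, long, six_tm,
    n_out, el_gt_il, gpcr_like (= n_out + el_gt_il).  The decoy is
    self-validated: its screening failure pattern must equal the union of
    the kinds' expected failures.
    """
    if isinstance(kinds, str):
        kinds = [kinds]
    kinds = list(kinds)
    if not kinds:
        raise ValidationError("at least one decoy kind required")
    for kind in kinds:
        if kind not in DECOY_KINDS:
            raise ValidationError(f"unknown decoy kind {kind!r}")
    expanded = []
    for kind in kinds:
        expanded.extend(["n_out", "el_gt_il"] if kind == "gpcr_like" else [kind])
    if "short" in expanded and "long" in expanded:
        raise ValidationError("short and long are mutually exclusive")

    tweaks: dict = {}
    for kind in expanded:
        tweaks.update(_DECOY_TWEAKS[kind])
    if "el_gt_il" in expanded and "short" in expanded:
        tweaks.update(loop_len_in_range=(10, 12), loop_len_out_range=(14, 18),
                      total_len_target=None)
    spec = GrlGeneratorSpec(seed=seed, **tweaks)
    record, truth = make_grl_like(spec, protein_id=protein_id, rng=None, validate=False)

    expected = set()
    for kind in kinds:
        expected |= _DECOY_FAILURES[kind]
    criteria = criteria or FilterCriteria()
    topo = predict_topology(record)
    result = apply_filters(record, topo, (), criteria)
    actual = {
        name
        for name in ("c1_reciprocal", "c2_length", "c3_seven_tm", "c4_n_in", "c5_il_gt_el")
        if not getattr(result, name)
    }
    if actual != expected:
        raise GeneratorError(
            f"{protein_id}: decoy {kinds} fails {sorted(actual)}, expected {sorted(expected)}"
        )
    truth = replace(truth, expected_failures=frozenset(expected))
    return record, truth


def make_cohort(
    n_positive: int,
    n_decoy: int,
    *,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, TopologyModel], dict[str, PlantedTruth]]:
    """A screening cohort: planted positives plus decoys violating >=2 criteria.

    Hierarchical seeding: each protein draws from its own substream, so
    growing the cohort leaves earlier proteins unchanged.  Returns the
    records (positives first), their predicted topologies, and the truth
    per protein id.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_positive + n_decoy)
    combos = [("short", "n_out"), ("gpcr_like",), ("six_tm", "el_gt_il"), ("long", "n_out")]
    records: list[ProteinRecord] = []
    truths: dict[str, PlantedTruth] = {}
    for i in range(n_positive):
        rng = np.random.default_rng(seeds[i])
        pid = f"pos_{i:03d}"
        rec, truth = make_grl_like(GrlGeneratorSpec(), protein_id=pid, rng=rng)
        records.append(rec)
        truths[pid] = truth
    for i in range(n_decoy):
        sub_seed = int(seeds[n_positive + i].generate_state(1)[0] % (2**31))
        pid = f"decoy_{i:03d}"
        rec, truth = make_decoy(combos[i % len(combos)], seed=sub_seed, protein_id=pid)
        records.append(rec)
        truths[pid] = truth
    topologies = {r.id: predict_topology(r) for r in records}
    return records, topologies, truths


def mutate_sequence(
    sequence: str, rate: float, rng: np.random.Generator,
) -> tuple[str, float]:
    """Point-substitute at ``rate``; returns (mutated, realized identity %)."""
    from grlscreen.io import AMINO_ACIDS

    out = list(sequence)
    changed = 0
    for i, a in enumerate(out):
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != a]
            out[i] = choices[rng.integers(len(choices))]
            changed += 1
    identity = 100.0 * (len(sequence) - changed) / len(sequence)
    return "".join(out), identity


def make_family(
    n: int,
    divergence: float = 0.3,
    *,
    indel_rate: float = 0.0,
    topology: str = "star",
    seed: int = 0,
    id_prefix: str = "fam",
    spec: GrlGeneratorSpec | None = None,
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """A protein family mutated from one generated ancestor.

    ``topology`` "star" mutates every member independently from the
    ancestor at ``divergence``; "two_clade" first derives two clade
    ancestors at ``divergence`` and then members at ``divergence / 4``.
    Realized pairwise identities are recorded in the truth (computed
    positionally; with ``indel_rate > 0`` small loop indels are applied
    after the identity bookkeeping, so recorded identities refer to the
    substitution process).
    """
    if n < 2:
        raise ValidationError("a family needs n >= 2")
    if not 0 <= divergence < 1:
        raise ValidationError("divergence must be in [0, 1)")
    root_seq = np.random.SeedSequence(seed)
    anc_rng = np.random.default_rng(root_seq.spawn(1)[0])
    spec = spec or GrlGeneratorSpec(seed=seed)
    ancestor, _ = make_grl_like(spec, protein_id=f"{id_prefix}_anc", rng=anc_rng,
                                validate=False)
    member_seeds = root_seq.spawn(n + 2)

    sequences: list[str] = []
    clades: list[str] = []
    if topology == "two_clade":
        clade_anc = []
        for c in range(2):
            rng = np.random.default_rng(member_seeds[n + c])
            mutated, _ = mutate_sequence(ancestor.sequence, divergence, rng)
            clade_anc.append(mutated)
        for i in range(n):
            rng = np.random.default_rng(member_seeds[i])
            clade = i % 2
            mutated, _ = mutate_sequence(clade_anc[clade], divergence / 4, rng)
            sequences.append(mutated)
            clades.append(f"clade{clade}")
    elif topology == "star":
        for i in range(n):
            rng = np.random.default_rng(member_seeds[i])
            mutated, _ = mutate_sequence(ancestor.sequence, divergence, rng)
            sequences.append(mutated)
            clades.append("star")
    else:
        raise ValidationError("topology must be 'star' or 'two_clade'")

    ids = [f"{id_prefix}_{i:02d}" for i in range(n)]
    identities: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            same = sum(a == b for a, b in zip(sequences[i], sequences[j]))
            identities[(ids[i], ids[j])] = 100.0 * same / len(ancestor.sequence)

    if indel_rate > 0:
        for i in range(n):
            rng = np.random.default_rng(member_seeds[i].spawn(1)[0])
            seq = list(sequences[i])
            k = 0
            while k < len(seq):
                if rng.random() < indel_rate:
                    if rng.random() < 0.5 and len(seq) > 50:
                        del seq[k : k + int(rng.integers(1, 4))]
                    else:
                        insert = "".join(
                            LOOP_IN_ALPHABET[rng.integers(4)]
                            for _ in range(int(rng.integers(1, 4)))
                        )
                        seq[k:k] = list(insert)
                        k += len(insert)
                k += 1
            sequences[i] = "".join(seq)

    records = [ProteinRecord(id=i, sequence=s) for i, s in zip(ids, sequences)]
    truth = PlantedTruth(realized_identity={"pairs": identities, "clades": dict(zip(ids, clades))})
    return records, truth


def make_gene_model(
    record: ProteinRecord,
    intron_positions: Sequence[tuple[int, int]],
    *,
    gene_id: str | None = None,
    intron_length: int = 120,
) -> GeneModel:
    """A gene model whose exon junctions plant the given introns.

    ``intron_positions`` are (codon, phase) pairs in protein coordinates
    (phase 0: intron after that codon; phase 1/2: intron inside it).  The
    gene axis inserts ``intron_length``-nt introns between exons.
    """
    cds_len = 3 * len(record)
    junctions = []
    for codon, phase in intron_positions:
        if phase not in (0, 1, 2):
            raise ValidationError(f"phase must be 0/1/2, got {phase}")
        c = 3 * codon if phase == 0 else 3 * (codon - 1) + phase
        if not 0 < c < cds_len:
            raise ValidationError(f"intron at codon {codon} phase {phase} outside CDS")
        junctions.append(c)
    junctions = sorted(set(junctions))
    if len(junctions) != len(intron_positions):
        raise ValidationError("intron positions must be distinct")
    bounds = [0] + junctions + [cds_len]
    exons = []
    offset = 0
    for start, end in zip(bounds[:-1], bounds[1:]):
        exons.append((start + offset, end + offset))
        offset += intron_length
    return GeneModel(
        gene_id=gene_id or f"{record.id}_gene",
        protein_id=record.id,
        exons=tuple(exons),
        strand="+",
    )


def make_bundle(
    *,
    n_helices: int = 7,
    residues_per_helix: int = 25,
    rise_per_residue: float = 1.5,
    twist_per_residue: float = 100.0,
    helix_radius: float = 2.3,
    ring_radius: float = 12.0,
    antiparallel: bool = True,
    noise_sigma: float = 0.0,
    seed: int = 0,
    bundle_id: str = "synthetic_bundle",
) -> tuple[CoordinateSet, PlantedTruth]:
    """An idealized C-alpha helix bundle with optional Gaussian perturbation.

    ``n_helices`` ideal alpha-helices (1.5 A rise, 100 deg twist per
    residue by default) stand on a ring of ``ring_radius``; with
    ``antiparallel`` every other helix runs in the opposite z direction,
    emulating the anti-parallel TM packing of the receptor fold.  Noise is
    i.i.d. Gaussian per coordinate with sd ``noise_sigma``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coords = []
    twist = np.deg2rad(twist_per_residue)
    height = (residues_per_helix - 1) * rise_per_residue
    for h in range(n_helices):
        ring_angle = 2 * np.pi * h / n_helices
        cx = ring_radius * np.cos(ring_angle)
        cy = ring_radius * np.sin(ring_angle)
        direction = -1 if (antiparallel and h % 2 == 1) else 1
        z0 = height if direction == -1 else 0.0
        for r in range(residues_per_helix):
            angle = twist * r + ring_angle
            x = cx + helix_radius * np.cos(angle)
            y = cy + helix_radius * np.sin(angle)
            z = z0 + direction * rise_per_residue * r
            coords.append((x, y, z))
    coords = np.array(coords, dtype=float)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    n = coords.shape[0]
    cs = CoordinateSet(
        id=bundle_id, residue_indices=tuple(range(1, n + 1)), coords=coords
    )
    return cs, PlantedTruth(noise_sigma=noise_sigma)
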