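# Methods

This note records the models, parameter choices, and numerical decisions
behind `grlscreen`, and what the synthetic-data experiments do and do not
demonstrate.

## Topology prediction

The predictor is a classic single-sequence hydropathy caller, not an HMM.
Per-residue Kyte–Doolittle values are averaged over an odd window
(default 19); positions within half a window of either end carry the
nearest full-window value, so profiles have no edge taper and reversing a
sequence mirrors its profile exactly.  X and any non-standard residue
score 0 (neutral).

Segments are maximal runs with windowed hydropathy ≥ 1.5, merged across
gaps of ≤ 3 residues, discarded under 15 residues, and trimmed
symmetrically to 30 (excess//2 removed from the left).  Window 19 /
threshold 1.5 / min-length 15 are the standard single-sequence TM-calling
parameters; all are keyword arguments.

Orientation follows the positive-inside rule: for both alternating side
assignments, K+R are summed over loops labelled "in" (N- and C-terminal
tails count as loops); the larger sum wins and ties go to an intracellular
N-terminus, the family's canonical orientation.

Two curation passes are available but **off by default**, because they
correspond to the manual curation topology servers need on this family
rather than to the base algorithm: `drop_reentrant` removes the first
segment when eight are called and the first sits within the N-terminal 60
residues (a membrane re-entrant helix mispredicted as a TM), and
`rescue_tm7` re-scans C-terminal of segment 6 at threshold − 0.5 when
exactly six segments are called (a subthreshold final TM).  Neither claims
to reproduce any external predictor's output.

## The retention screen

The five criteria are independent booleans; the verdict is
`n_passed ≥ min_criteria_passed`, default 4 of 5 — the explicit reading of
"most or all", chosen because real family members are retained despite
failing individual criteria (divergent motifs, subthreshold TMs).  The
"~350–500 aa" band carries an explicit slack parameter (default 30) rather
than a silent fudge, so the boundary is testable: 320 passes, 319 fails.
The reciprocal-hit criterion consumes a precomputed hit table (query,
subject, E-value, coverage, subject family); among rows passing E ≤ 0.05
and coverage ≥ 50%, the minimum-E row must be GRL/DUF3537, or no
qualifying row may belong to another family — an empty table passes, which
encodes "no significant similarity to other protein families".  The screen
is monotone: relaxing any single threshold never shrinks the retained set
(property-tested).

## TM7 motif scanning

The motif is scored per 9-mer window: four anchor positions (offsets 1, 2,
8, 9) against their residue sets, the five middle positions against the
hydrophobic class {A, C, F, I, L, M, V, W, Y} (the conventional set with
aromatics; configurable).  The anchor count ignores the hydrophobic run; a
flag records whether ≥ 4 of the 5 middle residues are in class h.  Only
the Y→F substitution at the second anchor is treated as conservative, and
only when requested; a conservatively-matched anchor counts toward the
total and is flagged as conservative.  X matches nothing.

The scan region is anchored to the last predicted TM segment: window
starts from (segment midpoint − 5) through (segment end + 10), the margin
covering prediction jitter and the motif's position toward the
extracellular end of TM7.  Ties between windows break toward more
hydrophobic-run matches, then the leftmost start.  The scanner is
property-tested against exhaustive enumeration with identical tie-breaks.

## Profile similarity

Families are condensed to pseudocounted position-probability profiles
(columns with > 50% gaps dropped; probabilities
(counts + pc·background)/(n + pc), pc = 1, uniform background by
default).  There are no insert/delete states: the analysis-level object is
the all-vs-all similarity matrix, not the profile HMM itself.

Pairs of profiles are aligned locally (Smith–Waterman over column pairs,
affine gaps 3/0.5) with the log-odds co-emission score
log₂ Σₐ p₁(a)·p₂(a)/q(a).  The normalized similarity is a logistic
transform of score per aligned column, with the column count floored at 30
so that short chance alignments cannot normalize high.  The logistic
constants (midpoint 2.0 bits/column, steepness 4) implement two
calibration contracts: self-alignment ≥ 0.99 and unrelated-profile
alignment ≤ 0.05 in expectation.  The midpoint sits where it does because
unrelated seven-TM families still share membrane-protein composition and
score ~1–1.3 bits/column against a uniform background, while self- and
within-family alignments score ~3.5–4.  These similarities are an
analogue of, not a substitute for, any external tool's homology
probabilities.

## Alignment, identity, and trees

Global alignment uses Biopython's pairwise aligner (BLOSUM62, gap open 11,
extend 1); identity is counted over columns where both rows carry a
residue.  The progressive MSA merges gapped blocks up an NJ guide tree
with a column-averaged substitution score and a flat per-column gap cost —
deliberately simple; its contract is that degapping recovers every input
exactly and columns never shrink.  Distances default to p-distance
(1 − identity/100), with optional Poisson correction; a > 50%-gap column
filter is the only trimming analogue provided.  Neighbor joining is the
standard Q-criterion agglomeration with ties broken by the smallest index
pair and negative branch estimates clamped to zero; NJ is exact on
additive metrics, which the tests exploit (random additive trees up to 8
taxa are recovered to machine precision, cross-checked against
scikit-bio's implementation).  Likelihood inference and branch supports
are out of scope.

## Structure comparison

Kabsch superposition is the closed-form SVD solution with the determinant
sign correction excluding reflections; degenerate (collinear) inputs are
handled by the same correction.  The TM-score uses
d₀ = 1.24·(L_ref − 15)^⅓ − 1.8 floored at 0.5 Å (L_ref ≥ 16), seeded on
the full correspondence and refined on pairs with dᵢ < 2d₀ to a fixed
point (≤ 20 iterations), reporting the maximum over iterations.  The
correspondence comes from a sequence alignment or an explicit index map —
there is no structural alignment search.  Classification bands: ≤ 0.30
random, ≥ 0.5 same fold.  In the pairwise matrix the TM-score is
normalized by the row structure's length, so both orientations of every
pair are reported (the matrix may be asymmetric); RMSD is symmetric.
Model-intake filters (minimum 15 MSA sequences, minimum estimated
TM-score 0.17) apply to metadata supplied alongside coordinate files.

## Introns

An intron's phase is the cumulative CDS length at the exon junction
mod 3.  Phase-0 introns are recorded at the boundary after the last
complete codon (residue c/3); phase-1/2 introns at the codon they split
(⌊c/3⌋ + 1).  Projection through an MSA maps the residue index to its
alignment column (monotone by construction).  Sharing requires equal phase
and columns within ± tolerance; the default tolerance is 0 columns —
strict by default, with the knob making looser readings reproducible.
Minus-strand gene models are normalized to CDS orientation at parse time.

## Synthetic data: what it emulates, and what it does not

The generators produce the study conditions the pipeline is tested under:
seven-TM proteins of 350–500 aa with intracellular N-termini and IL > EL
loop structure, a TM7 motif with a controllable number of conserved
anchors, decoys violating named criteria, families at controlled
divergence, gene models with introns at chosen codons/phases, and
idealized helix bundles (1.5 Å rise, 100°/residue twist, ring radius
12 Å, antiparallel packing) under Gaussian coordinate noise.

Composition is designed so planted truth is decisive at noise 0: TM
stretches draw from L/I/V (the motif-bearing TM from I/V outside the
planted window, so no spurious anchors enter the scan region); inside
loops carry K and R at 4× the density of outside loops, which carry R
only; loops avoid anchor residues entirely.  TMs default to 23–26 aa
(26–28 for the motif TM, whose polar anchors dilute the hydropathy
signal) and extracellular loops to ≥ 10 aa — under a 19-residue window,
shorter TMs leave above-threshold runs under the 15-residue minimum and
shorter loops cannot separate adjacent TMs, so these are the shortest
architectures the default predictor can resolve, and the generator's
realism claim is limited accordingly.  Every generator self-validates its
planted truth against the consuming module before returning, and a single
seed drives per-protein substreams so cohorts are stable under growth.

Real sequences differ in ways the generator does not emulate: mixed-
composition TMs near the calling threshold, anchor-like residues adjacent
to the motif, loop-length and composition heterogeneity, indel-rich
alignments.  Passing tests therefore demonstrate the correctness of the
decision logic and algorithms under clean planted signals, not predictor
accuracy on biological sequences.

## Problem sizes

The test suite and acceptance script run at desk scale by design: cohorts
of 4–20 proteins, families of 3–8 members (three-TM, ~150–250 aa variants
for profile and intron tests), 100-seed generator sweeps, bundles of
175–406 residues, additive trees to 8 taxa, and 1000-sequence motif-oracle
sweeps.  These sizes were chosen as the smallest that exercise every
contract; all results printed in the README were produced by the scripts
shown there.
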