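# Methods

This note documents the models, decision rules, numerical choices and
known limitations of kinprof, and states what the synthetic-data
generators do and do not emulate.

## Selectivity grouping

Panel tables carry percent remaining kinase activity per (kinase,
compound). Classification is purely threshold-based: inhibited iff
activity ≤ `inhibited_cutoff` (default 50%), non-inhibited iff ≥
`noninhibited_cutoff` (default 99%), both boundaries inclusive; the open
band in between is kept as an explicit `unclassified` set so reports can
show how many kinases fall between the two cutoffs rather than silently
discarding them. Duplicate measurements of a pair are averaged (the SEM
of the first record is retained for reporting). Kinase identifiers are
compared case-insensitively after whitespace stripping; no alias
dictionary is consulted, so spelling variants beyond case remain
distinct.

## Conservation scoring

The scorer is deliberately tree-free and deterministic (method tag
`jsd-henikoff-v1`):

1. **Weights.** Henikoff–Henikoff position-based weights: in each column
   a sequence holding one of *s* copies of a residue type receives
   1/(r·s), where *r* is the number of distinct non-gap types; weights
   are normalized to sum 1. This neutralizes redundant sequences without
   requiring a phylogeny.
2. **Scores.** Per column, the Jensen–Shannon divergence (base 2) between
   the weighted residue distribution and a background distribution,
   multiplied by the column's weighted non-gap fraction. Gaps are never a
   21st symbol; the non-gap scaling ensures a gappy column cannot outrank
   a full column of equal composition, and a fully gapped column scores
   exactly 0. The default background is the Robinson–Robinson frequency
   table (packaged, overridable).
3. **Grades.** Ranks of the scores are split into 9 equal-count bins,
   grade 9 = top bin; tied scores share the grade of their first
   occurrence in rank order, and an all-equal profile collapses to the
   neutral midpoint grade 5. Grading is therefore relative to the
   alignment at hand, which matches how 1–9 conservation scales are used
   in practice, but means grades are not comparable across unrelated
   alignments — only grade *differences* between two groups aligned to
   the same reference are interpreted downstream.
4. **Confidence.** A column is flagged low-confidence when fewer than 6
   sequences carry a residue there, or when the central 95% interval of
   its grade across 200 bootstrap resamplings of the sequences (with
   replacement, explicit seed required) spans more than 3 grades. The
   bootstrap construction is this package's own definition of the
   interval; the replicate count trades runtime against flag stability
   and 200 was fixed once for all analyses.

Pairwise identity to the reference counts only columns where both
sequences are non-gap. Column-to-residue mapping assigns the k-th non-gap
reference position the author number `first_residue + k − 1`.

This scorer is a stated substitution for phylogenetic Bayesian rate
estimation (ConSurf-style). Consequently absolute grade values are
method-dependent: group-differential grade deltas from this package are
qualitative signals, not reproductions of any published per-residue
grade, and the package never asserts numeric equality with externally
computed grades.

## Differential screen

Delta = grade(inhibited) − grade(non-inhibited), so a residue conserved
in the inhibited group but variable in the other appears positive;
filtering is on |delta| ≥ `min_delta` (default 3). Residues flagged
low-confidence in either profile are omitted by default; residues covered
by only one profile are reported separately, never silently dropped.
Default region spans (AMPKα2 numbering) delimit the N-lobe (6–93), an
ATP-pocket ring (hinge 94–100 plus catalytic loop 140–150), the
activation loop (157–182) and the C-lobe helices (101–139, 151–156,
183–280). The four regions are named structural clusters whose exact
boundaries are not canonical; the shipped spans were chosen to be
pairwise disjoint (the module rejects overlapping spans) and are fully
editable via YAML.

## Structure geometry

Files are parsed with gemmi. Normalization: hydrogens removed; one
conformer kept per atom name by highest occupancy, ties resolved to the
alphabetically first altloc; author (PDB) residue numbering used
throughout; default chain `A`. Distances are Euclidean in Å; reporting
rounds to one decimal while computation keeps full precision.

Dihedrals follow the IUPAC convention — Φ(i) = torsion(C(i−1), N(i),
Cα(i), C(i)), Ψ(i) = torsion(N(i), Cα(i), C(i), N(i+1)) — in the range
(−180°, 180°]. Angles at chain termini are explicit missing markers, and
a peptide C–N distance above 2.5 Å is treated as a chain break (angle
missing, warning emitted).

Disulfides: all cysteine Sγ–Sγ pairs within 2.3 Å, matched greedily
nearest-first so each cysteine joins at most one bond. Regulatory spine:
for each consecutive pair in the ordered spine set, the minimum distance
over side-chain heavy atoms (backbone N/Cα/C/O excluded); the spine is
broken iff any link exceeds 4.5 Å, and a residue with no side-chain
heavy atoms breaks its link. The default spine set for AMPKα2 (αC Leu68,
DFG Phe158, HRD His137, αF Asp196) is editable data, as is every anchor
residue (β3 Lys45, αC Glu64, D1 anchor Leu68, DFG 157–159, x-DFG-x
156–160, gatekeeper Met93, disulfide candidates Cys106/Cys174).
Anchor validation requires only the residues the measurements need;
gatekeeper and HRD are descriptive and optional.

Superposition is the closed-form Kabsch solution (SVD with determinant
correction, guaranteed proper rotation); fewer than three pairs or a
collinear point set is rejected as degenerate.

## Conformational calls

The spatial rule and its defaults — DFG-out iff D2 ≤ 11 Å; DFG-in iff
D2 ≥ 11 Å and D2 − D1 ≥ 2 Å; else DFG-inter — were chosen so that the
three published AMPKα2 inhibitor structures (D1 11.4–13.1 Å, D2
16.6–18.4 Å) all label DFG-in, consistent with their published
description; the exact decision boundaries of the originating
nomenclature are not restated in the source material, so the constants
are configurable and every call echoes `thresholds_used`. The αC call is
out iff the Lys–Glu distance strictly exceeds 10 Å (a broken salt
bridge).

Dihedral clustering assigns the x-DFG-x window to the nearest centroid by
mean per-angle circular distance (wraparound respected; missing terminal
angles excluded with renormalization) and returns `unassigned` when that
distance exceeds 45°. The packaged centroid library is an approximate
curated transcription of the published kinase structural-state
nomenclature; it is data, not code, and should be replaced with exact
centroids where available. The 45° cutoff is permissive enough to assign
textbook states while keeping genuinely novel backbones unassigned.

## Curve models

Both fits minimize unweighted least squares (replicates pooled), with
bounds Kd, IC50 > 0 and Bmax ≥ 0, initialization from the data
(background = min Y, Bmax = range, Kd at the half-rise, NS from the
terminal slope; logistic top/bottom from response extremes, IC50 at the
half response, Hill ±1 by direction), standard errors from the Jacobian
at the optimum, and an honest `converged` flag — degenerate inputs (flat
response) are returned flagged rather than raised. Dose-response fits
drop zero concentrations (undefined on a log axis, with a warning) and
canonicalize top ≥ bottom. IC50/Kd are reported in the input
concentration unit. The dilution helper builds the 1:1 serial design
(default 250 µM top, 16 points); note a 16-point 1:1 series bottoms out
at ~0.0076 µM while a 15-point series gives the commonly quoted
~0.015 µM floor — both are expressible via `n_points`.

## Synthetic data

Generators are pure functions of their arguments with a mandatory seed.

* **Panels** draw activities strictly inside the label-defining intervals
  (inhibited ≤ 50, non-inhibited ≥ 99, the rest strictly between), so the
  planted partition is recoverable exactly. Defaults emulate a
  140-kinase screen with 7 inhibited and 10 non-inhibited kinases.
* **MSAs** plant per-column conservation: conserved columns carry a
  single residue, variable columns sample uniformly from a 10-residue
  alphabet, and intermediate columns hold a majority residue at fraction
  0.7 — real kinase-domain alignments are dominated by such
  mid-conservation positions, and because the 1–9 grades are rank bins,
  a recovery benchmark needs that realistic bulk: extreme columns can
  only occupy the extreme grade bins when they are a minority. The
  planted-recovery conditions used by the tests are 20 conserved + 20
  variable columns on a 50-intermediate background in 50 sequences.
* **Structures** are built by sequential internal-coordinate placement
  with ideal bond lengths/angles (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
  1.329 Å; angles 111°/117°/121°; ω trans), so planted Φ/Ψ are
  reproduced to well below 1e-6°. Side-chain atoms exist only where a
  measurement needs them: planted Sγ pairs at a stated distance, anchor
  atoms placed to realize stated D1/D2/Lys–Glu distances exactly, and
  one Cβ per spine residue at stated spacings. These are geometric
  fixtures, not physical proteins — no sterics, no rotamers, no
  crystallographic noise. The `reference_standin_structure` helper builds
  such a fixture from the packaged table of published measurements; it
  validates the measurement code against the published numbers but does
  **not** validate anything about the real crystallographic coordinates.
* **Curves** combine the serial-dilution design with model predictions
  plus Gaussian noise (the simplest defensible error model for ratio
  readouts; real titrations can have concentration-dependent variance
  that is not emulated).

Passing the planted-recovery tests therefore demonstrates correctness of
the measurement and inference machinery under ideal, noise-controlled
conditions; it does not demonstrate robustness to disorder, missing
atoms, alternative conformations beyond the altloc rule, or alignment
error in real data.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path: 140-kinase panels, 40–50-sequence alignments of ~90 columns
with 60–200 bootstrap replicates, 7–10-residue toy structures, 1000-case
dihedral and cluster-assignment sweeps, and 100-repeat Monte-Carlo fit
studies at 2% noise.

## Known limitations

* Conservation grades are relative and method-dependent (see above).
* The dihedral cluster centroids are approximate curated stand-ins.
* The spatial DFG thresholds are calibrated to three published structures
  of one kinase; applying them kinome-wide should be done with the
  thresholds revisited.
* Identity and conservation operate on the input alignment as given; no
  realignment or alignment-quality assessment is performed.
* The regulatory-spine default set is a four-residue approximation of the
  canonical spine definition.
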