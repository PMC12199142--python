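# Methods

## The model

RNA secondary structures decompose into stems (runs of stacked canonical
base pairs) and the loops they close. Local stability compensation (LSC) is
the hypothesis that a destabilizing loop is offset by its *immediately
adjacent* stem(s) rather than by helices elsewhere in the structure. The
central statistic is the net free energy of a loop,

    net dG = dG_loop + dG_stem                      (hairpin loops)
    net dG = dG_loop + (dG_stem1 + dG_stem2) / 2    (bulges, internal loops)

in kcal/mol at 37 °C, where the two-way-junction form averages the full
(not per-base-pair) free energies of the two flanking stems.

## Component free energies

Substructure energies follow the Turner 2004 nearest-neighbor rules. The
tables (stacking, loop initiations, terminal mismatches, 1×1/2×1/2×2
internal-loop tables, Ninio asymmetry, AU/GU end penalty, special
tri/tetra/hexaloops) are shipped as plain-text assets transcribed from the
published set, stored as integers in units of 0.01 kcal/mol. Loops larger
than the tabulated maximum of 30 nt are extrapolated with the
Jacobson–Stockmayer term `init(30) + 1.75·R·T·ln(n/30)`; the log term is
truncated to an integer (in 0.01 kcal/mol), matching the integer-table
convention of standard evaluators.

Because a nearest-neighbor total is a sum over *loops*, not over helices,
terms shared between a stem and its neighboring loop need a home. The
assignment here keeps each loop's energy self-contained and makes the
component sum equal the standard total for single-branch structures
(verified against an independent evaluator with dangling ends disabled):

* stems: stacking terms, plus the AU/GU end penalty only at ends facing an
  unscored region (exterior loop or multiloop);
* hairpins: initiation, terminal mismatch (size ≥ 4), special-loop
  energies, AU/GU closure for size-3 loops;
* bulges: initiation; size 1 additionally carries the through-helix
  stacking term, size ≥ 2 the AU/GU penalties of both closing pairs;
* internal loops: exact tables for the small special cases, otherwise
  initiation + Ninio asymmetry (coefficient 0.6, cap 3.0 kcal/mol) +
  per-side terminal mismatches.

Multiloop, exterior-loop, and dangling-end terms are never computed: the
analysis scores only hairpins, bulges, internal loops, and stems, so a
total energy is defined (and tested) only for single-branch structures.
Components touching non-canonical pairs or ambiguous bases (N), and
hairpins of size < 3, are marked unscorable and reported, never silently
zeroed. Special C-loop bonus terms that some parameter distributions add
are not part of the shipped table set.

## Database statistics

* **Binned regressions.** Records are binned by loop dG (left-closed bins,
  0.25 kcal/mol wide); the per-bin stem-dG aggregate (median or the
  5% quantile, linear-interpolation method) is regressed by OLS on bin
  centers. Bins with fewer than 10 records are excluded from the fit.
* **Rotation control.** Within each structure contributing ≥ 4 loops of a
  type, loops ordered 5'→3' are re-paired with the stems of the loop a
  cyclic shift of ⌊k/2⌋ away (incremented until no loop receives one of its
  own stems). Compensation makes the true net-dG variance smaller than the
  control's; the two-sided variance F-test (unbiased estimators,
  F(n−1, n−1)) quantifies it.
* **Distributions.** Gaussian KDE with Scott's-rule bandwidth; group
  summaries report the median and (n−1) SD, with two-sided Mann–Whitney U
  tests for pairwise contrasts (a deliberate, replaceable choice for an
  unnamed nonparametric comparison).

## Library design

Constructs are triply-bulged hairpins: four stems S1–S4 separated by three
single-stranded slots, unpaired 5'/3' flanks, and one variable region
(apical hairpin + S4; or the middle slot as a bulge or internal loop +
S2/S3). Constant-energy stems use G:C/C:G closing pairs, a fixed GC
fraction (default 0.6 where feasible; 0.5 for even lengths in the SD
benchmark) and no G:U pairs; over 1,000 resamples at fixed length their
free-energy SD stays below 0.5 kcal/mol. Variable stems draw length
(4–12), GC fraction (grid 0–1) and G:U count (0–3); loops use the {A, C}
alphabet, sizes 3–11 (hairpin), 1–9 (bulge), 1–9 total split across sides
(internal). Including GC-free stems and up to three wobble pairs is what
lets hairpin-library net dG span [−15, +5] kcal/mol and beyond.

Libraries enforce a pairwise sequence distance ≥ 20. For unequal lengths,
distance = positional mismatches over the shorter sequence + the length
difference; this equals Hamming distance on zero-padded encodings, which is
how the all-pairs check is vectorized. After generation, constructs outside
±20% of the realized mean length are filtered out. Generation is
deterministic given the seed.

## Reactivity analysis

DMS methylates accessible A/C nucleotides, so all reactivity summaries are
restricted to A/C positions. Folding fidelity is the AUROC separating
designed-unpaired (positives) from designed-paired (negatives) nucleotides
by reactivity, computed with midranks, in global/local/distal scopes; it is
undefined (None, not an error or a degenerate 0/1) with fewer than two
positives or two negatives. Constructs containing more than four
consecutive C residues are removed before analysis. Mean stem/loop
reactivities use raw mutation fractions (no normalization — AUROC is
rank-invariant to it anyway); log transforms add a 1e-4 pseudocount.
Per-position profiles average each base pair's A/C reactivities, counting
pairs outward from the loop (position 1 = closing pair, up to 6); for
two-way junctions a position contributes only where both stems have a pair
there. Bins with fewer than 70 contributing nucleotides are suppressed;
intervals are normal-approximation 95% CIs.

## Hill fit and the 0.9 threshold

Local AUROCs are averaged in 0.2 kcal/mol net-dG bins and fitted to

    f(s) = A0 + (1 − A0) · s^h / (s50^h + s^h),   s = 10 − net dG,

by bounded nonlinear least squares (A0 ∈ [0.3, 0.9], h ∈ (0, 20],
s50 ∈ (0, 30]). The offset 10 maps the observable net-dG range onto a
positive stability axis; the plateau is fixed at 1 and the baseline fitted.
Bin means are weighted by √count by default: a bin mean's variance scales
as 1/count, and unweighted fits let sparse tail bins wander the strongly
correlated (A0, h, s50) ridge (the 0.9 crossing is robust either way; the
midpoint is not). The threshold g09 is the net dG where the fitted curve
crosses AUROC 0.9, solved in closed form from the parameters; it is
undefined if the fitted curve stays below 0.9 over the data range.

## Synthetic data

* **Substructure database.** Loop dG ~ exponential (scale 3) truncated to
  [0.5, 12] kcal/mol — loop penalties are small-positive-skewed; stem dG =
  α·loop + β + N(0, σ²) per adjacent stem (defaults α = −0.8, β = −2,
  σ = 1, values in the range the binned regressions estimate), with
  optional additive family offsets. Records group into structures of 5
  loops so rotation-control eligibility holds.
* **DMS model.** Two-state local unfolding: the variable region folds with
  probability s^h/(s50^h + s^h) (defaults h = 4, s50 = 14, offset 10,
  putting the AUROC=0.9 crossing near −10 kcal/mol, inside the range the
  designed libraries cover densely). Paired and unpaired nucleotides draw
  true rates from log-normals with means 0.01 and 0.10 (typical DMS
  mutation-fraction scales, log-SD 0.5); local stem positions draw from the
  unpaired distribution with the unfolding probability, distal positions
  always follow their designed state — the locality assumption the distal
  regression then tests. Observed reactivity adds binomial counting noise
  at Poisson read depth (mean 5000). A cosmetic ×0.8 depression of folded
  loop reactivity is available but excluded from recovery benchmarking:
  with it active the expected AUROC curve is quadratic, not Hill-form, in
  the folded fraction.
* **Oracle curve.** `expected_auroc_curve` integrates the mixture + depth
  noise by Monte Carlo (≥ 1e5 draws per grid point) to give the expected
  AUROC at any net dG, independently of the per-construct pipeline.

What the simulations do not emulate: sequence-dependent reactivity biases,
partial/ensemble folding states (the two-state mixture is a modeling
choice), register-shifted misfolds, alignment or demultiplexing artifacts.
Passing recovery tests therefore demonstrates the estimators are correct
under the stated generative model, not that real libraries obey it.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen to give
stable statistics in minutes on one CPU: 120 random structures for the
energy oracle, 1,000 instances for the AUROC oracle, 20,000 records for
slope recovery, 2,000 records / 100 null replicates for the rotation
control, 20 libraries × 3,000 constructs for Hill recovery, and a
1,000-construct library for the design-constraint audit. Ties in AUROC are
midranked; quantiles are linear-interpolation (type 7); all RNG flows from
explicit seeds (numpy `default_rng` / `random.Random`) and reruns are
byte-identical.

## Known limitations

* Pseudoknot pairs are dropped to unpaired at parse time (with a warning);
  pseudoknot energetics and page assignment are out of scope.
* Energies are 37 °C free energies only; no enthalpies, no temperature
  scaling, no coaxial stacking, no ligand or tertiary corrections.
* Structure prediction itself is out of scope: the constraint exporter
  writes standard hard-constraint strings for an external folding engine,
  and refolded structures re-enter through the dot-bracket parser.
* Total energies are defined only for single-branch structures, because
  multiloop/exterior terms are deliberately never computed.
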