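# Methods

## Steady-state Thr model

Free Thr per cell follows a single ODE with Michaelis–Menten production
from two threonine synthases fed by a constant substrate supply `S`
(*O*-phosphohomoserine) and first-order usage `δ`:

    d[Thr]/dt = S·( E_M/(Km1+E_M) + E_T/(Km2+E_T) ) − δ·[Thr]

`E_M` and `E_T` are MTO2 and TSY2 expression (arbitrary units, treated
as proportional to enzyme activity), and `Km1`, `Km2` are the activity
levels at which production is half-maximal.  The steady state is the
closed form `Thr* = P/δ`, bounded by `2S/δ`.  Wild-type
parameterizations enforce `Km2 ≥ 100·Km1` (MTO2 activity two orders of
magnitude above TSY2); the *mto2-2* genotype removes the MTO2 term and
divides `Km2` by `tsy2_compensation` (default 100) to represent
compensatory TSY2 activity.

The extended variant adds catabolism: with `a = E_THA/(Km3+E_THA)` and
`b = E_OMR/(Km4+E_OMR)`,

    d[Thr]/dt = P − a·Thr − b·Thr·Km5/(Km5+Ile) − δ·Thr
    d[Gly]/dt = a·Thr − δ·Gly
    d[Ile]/dt = b·Thr·Km5/(Km5+Ile) − δ·Ile

`Km5` sets the Ile level at which OMR1 inhibition is half-maximal.  At
steady state the system reduces to one scalar balance in Ile whose
residual is strictly decreasing, positive at 0 and negative at the flux
bound `b·P/δ²`; it is solved with Brent's method (xtol 1e-12).  With
zero catabolic expression the extended model reduces exactly to the
synthesis-only closed form; the test suite verifies agreement with
long-time ODE integration to 1e-6 relative on random parameter sets.

**Expression gradients.**  Expression is linear in normalized position
x ∈ [0, 1] (0 = quiescent centre), clamped at zero:
MTO2 10 − 10x, TSY2 1 + 9x, THA1/2 and OMR1 8 − 8x, each with a `scale`
multiplier for scaling experiments.  The coefficients are model inputs
(exposed in `default_gradients`), chosen to reproduce the qualitative
tip-high MTO2 / tip-low TSY2 patterns; regression against transcriptome
data is out of scope.

**Default kinetics.** `S = 1`, `δ = 1`, `Km1 = 10`, `Km2 = 1000`
(satisfying the 100-fold constraint), `Km3 = Km4 = Km5 = 10`.

**Whole-root content.** A grown root is mostly differentiated tissue
shootward of the modelled axis, where the profile takes its x = 1 value.
`whole_root_thr` therefore integrates the profile over the axis and
adds `tail_weight · Thr(1)` (default 10 axis lengths).  This is what
makes the mutant/wild-type ratio exceed 1.5 despite the mutant's tip
deficiency: TSY2-driven production peaks in the differentiated zone.
The simulator computes the same quantity exactly (midpoint Thr × cell
length summed over all cells), with no tail approximation.

**Sweeps.** Latin-hypercube sampling over Km 1–1000 and δ 1–10
(synthesis) plus Km3/Km4/Km5 1–100 (extended), mirroring the published
exploration sizes of 10,000 and 125,000 sets (tests and the acceptance
suite use 100–1,000 sets; the sampled fractions are stable at that
size).  Wild-type draws violating `Km2 ≥ 100·Km1` are resampled
uniformly.  A set is accepted when the whole-root ratio is ≥ 1.5 and
the mutant SCN level is below wild type.

## Lattice root simulator

Each of four tissue files is a column of cells; a cell is a contiguous
run of integer grid rows anchored at the QC.  Zone boundaries are fixed
in the QC-anchored frame and derived from the initial geometry:
QC + stem initial (birth length each), 32 PD cells, 8 TD cells (RAM =
40 cells), 8 elongation-zone cells graded upward from twice the birth
length by `ez_increment`, a partially elongated tail, and two
differentiated cells at `final_length`.  Both genotypes share this
initial condition.

Per step (dt = 0.1 a.u., t_max = 5):

- QC cells are inert.
- The stem initial grows one row every second step
  (`stem_cycle_factor = 2`) and, once doubled and Thr-permitted,
  divides asymmetrically: rootward daughter stays a stem cell,
  shootward daughter becomes transit-amplifying (TA) with a five-cycle
  capacity; daughters of TA divisions inherit `divisions_used + 1` and
  become exhausted at five.
- RAM cells grow one row per step **up to twice their birth length**.
  The doubled size is treated as cycle completion: a cell that cannot
  divide (Thr gate, exhausted capacity, or TD position) arrests there
  until displaced.  Without this arrest the mutant root would keep
  creeping indefinitely and never show the observed growth plateau.
- A TA cell in the PD with doubled length divides into two halves (odd
  row to the rootward daughter) if Thr at its midpoint is ≥ θ.
- Cells displaced past the RAM boundary elongate by `ez_increment` rows
  per step and differentiate at `final_length`.
- Positions are recomputed by exact tiling after every step
  (displacement by growth of rootward neighbours).

**Thr gate θ.** Default: half the wild-type SCN steady-state Thr under
default parameters (≈ 0.2505).  Wild-type PD Thr stays above θ
(divisions proceed); mutant Thr is below θ throughout the PD (no
divisions), which with the finite TA capacity yields determinate
growth.

**Position → gradient mapping.**  Cell midpoint grid distance divided
by `td_end / 0.17`, clamped to [0, 1]: the RAM occupies the apical ~17%
of the gradient axis, the fraction it has in the default initial root.
Anchoring the axis to the RAM extent (rather than to the initial root
length) keeps the zone layout gradient-invariant across the cell-growth
parameter sweeps, consistent with zone lengths proportional to real
seedlings; for the default geometry the two mappings agree to ~2%.

**Growth classification.**  A trajectory is determinate when relative
total-length increase over the trailing 1 a.u. falls below 0.1%
(plateau); the classification is invariant to halving dt.

**Statistics.**  Cell-length distributions are compared with the
two-sided Mann–Whitney U test (tie-corrected normal approximation —
simulated lengths are heavily tied) and the unpaired two-tailed
Student's t-test.  The t1–t2 window is the contiguous run of recording
times where mutant RAM vs wild-type TD gives p > 0.05, choosing among
runs the one with the most simultaneous separation from the PD
(p ≤ 0.05): at early times the genotypes are still identical cell for
cell, so both comparisons are trivially non-significant and that run is
not the window of interest.  With defaults the window is t ∈ [3.1, 3.3]
with PD separation at every time inside it.

**Robustness.**  The four shared features (Wt indeterminate / mutant
determinate; mutant whole-root Thr higher; mutant SCN Thr lower;
non-empty indistinguishability window) hold on the full grid of
division thresholds {2,4,6,8,10} × elongation increments {3..8} ×
final lengths {75,80,85,90}; the acceptance test runs a 2×2×2 sub-grid
({4,6} × {5,8} × {80,90}) to keep the default suite fast.  Whole-root
Thr is compared at 0.68·t_max (t = 3.4 with defaults), a matched
mid-growth time inside the mutant's pre-plateau window.

**Expression scaling.**  Gradient `scale` is varied with θ held at its
unscaled default: scale 0 stops wild-type growth (no Thr production);
scale ≈ 10 restores indeterminate growth in the mutant.

The simulator is deterministic; the config seed is recorded in
manifests and reserved for stochastic extensions.

## MSC zonation

Per-segment OLS (intercept + slope on 1-based cell index) with global
RSS minimized by dynamic programming over admissible segment ends
(every segment ≥ h cells); segment costs come from prefix sums, so a
fit is O(m·n²).  Exact RSS ties resolve to the earliest admissible
previous segment end; BIC ties resolve to the smaller m.

- `f = ceil(300/n_s)/100`: the smallest two-decimal fraction with
  `f·n_s ≥ 3` (smallest-profile sizes 25, 24 and 13 give 0.12, 0.13 and
  0.24).  Computed per sample; a single root is its own sample.
- `h = max(3, floor(f·n))`, computed in integer arithmetic; inputs with
  `h ≥ n/2` raise rather than clamp.  The smallest admissible profile
  has 7 cells and the smallest attainable h is 3.
- BIC uses the Gaussian log-likelihood
  `LL = −(n/2)(log 2π + log(RSS/n) + 1)` with
  `npar = 2(m+1) + m + 1` (segment coefficients, breakpoints, error
  variance); a zero-residual fit scores −∞ so noiseless profiles always
  select their true m.  The breakpoint-count convention of other
  segmented-regression implementations may differ by a constant offset;
  selection behaviour, not absolute BIC, is the validated contract.
- Annotation: m = 2 → PD|TD|EZ; m = 1 → TD|EZ (the whole RAM behaves as
  a TD); m = 0 → undetermined.  Wild-type mode forces m = 2 per root.

## Synthetic profiles

Piecewise-linear means with additive Gaussian noise (default σ = 0.4
µm, small against PD cells of ~4.5 µm), truncated at 0.5 µm; presets:
wt_like 25 PD cells (4.5 µm, slope 0.05) + 10 TD (6.0, 1.5) + 12 EZ
(21.0, 12.0); mto2_like 12 TD-like (6.0, 1.5) + 10 EZ (24.0, 12.0);
exhausted one 20-cell monotone segment (6.0, 6.0).  Segment start
lengths continue the preceding regime, so junctions are slope changes,
not jumps — as in real profiles.  Cohorts jitter segment counts, start
lengths and slopes by a truncated-normal factor (CV 0.1).

What the generator does **not** emulate: measurement autocorrelation
along a root, non-Gaussian digitization error, curvature within
regimes, and any coupling between neighbouring cells.  Passing tests
therefore show that the segmentation recovers piecewise-linear
structure under independent noise, not that real roots are
piecewise-linear.  One consequence worth knowing: because the presets
are continuous at the junctions, BIC splits a third "knee" segment in
roughly a quarter of noisy 2-regime profiles — close to the ~29%
two-breakpoint share reported for real mutant roots — so 2-regime
cohorts classify as m = 1 by majority, not unanimously.

## Numerical and design notes

- Extended steady state: Brent root-finding on a guaranteed bracket; no
  iteration-budget failures are reachable for positive parameters.
- Mann–Whitney approximation accuracy: within 0.02 of exact enumeration
  for tie-free samples of 5–8; below n = 5 the normal approximation
  itself deviates by up to ~0.04 at mid-range U, a property of the
  approximation, not of this implementation.
- Division tie-break: odd parent rows go to the rootward daughter
  (deterministic; keeps tip-proximal cells marginally larger).
- Zone membership is decided by cell midpoint; QC and stem initials are
  SCN, excluded from PD/TD/RAM/EZ+DZ length collections.
- Degenerate statistics: identical samples return p = 1 for both tests;
  zero-variance samples with distinct means return t-test p = 0.

## Problem sizes

Default test and reproduction runs use 50-step simulations (~250 cells
per file at t = 5), sweeps of 100–1,000 parameter sets, cohorts of 100
profiles and oracle checks of 100–200 random instances.  These sizes
give stable fractions and exact oracle agreement while keeping the full
suite under half a minute.
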