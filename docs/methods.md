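# Methods

## Regeneration ODE

The model tracks fractions H1, H2, H3 of the HBC pool in G1, S and
G2/M, and the differentiated-cell abundance D (arbitrary units; only
D/K enters the dynamics, so the absolute scale of D and K is
irrelevant).  Division returns one daughter to G1 and adds one
differentiated cell, so H1+H2+H3 is conserved exactly and is normalized
to 1.  The G1→S rate is feedback-inhibited by D through a Hill
function, k1 = kmax/(1+(D/K)^h): an injured tissue (D ≈ 0) proliferates
at kmax, a regenerated one shuts back down.  Time is in days
throughout; fractions are 0–1 internally and percentages only at I/O.

Parameters and defaults (the fitted post-injury set):

| parameter | default | units | meaning |
|---|---|---|---|
| kmax | 2.27 | 1/day | maximal G1→S rate at D = 0 |
| k2 | 1.33 | 1/day | S→G2/M rate (S phase ≈ 18 h); fixed, not fitted |
| k3 | 6 | 1/day | division rate (G2/M = 4 h); fixed, not fitted |
| γ | 0.06 | 1/day | turnover of differentiated cells |
| K | 0.4 | a.u. | feedback half-saturation in D |
| h | 2 | — | Hill coefficient, integer-constrained in fits |
| τ | 0.8 | day | post-injury activation delay |

**Basal state.**  Data pin only the basal S-phase fraction
(H2 = 0.065, the uninjured p63+/EdU+ fraction) and D = 0.  H3 and H1
are completed by the pre-injury flux balance k2·H2 = k3·H3 with the
pool normalized to 1 — "basal levels" is read as a quasi-steady state
of the cycling compartments.  **Delay.**  All four components,
including D, are held at their initial values for t < τ; letting D grow
while H3 is held would be internally inconsistent (D is fed only by
division, which the delay suspends).

**Numerics.**  LSODA with rtol 1e-8 / atol 1e-10, integrating on
[τ, t_max] with the hold-phase prepended analytically; sub-atol
negative excursions are clamped to 0.  The test suite checks the solver
against an independent fixed-step RK4 oracle (1e-4-day steps) to
< 1e-5 in every component, and conservation of H1+H2+H3 to 1e-6.

**Fitting.**  Unweighted least squares of model H2(t) against observed
EdU+ fractions (counts are converted as n_positive/n_cells), with
multi-start trust-region refinement for the continuous parameters and,
when h is freed, an outer search on the integer grid {1,2,3,4}
(the fitted value h = 2 is exactly integer, suggesting the constraint).
A crude flat-objective probe warns when a freed parameter has no
leverage (e.g. data only before τ).

## Sister-chromatid partitioning mixture

Per cell: symmetric with probability ps (X1, X2 ~ N(1, σ) i.i.d.) or
asymmetric (X1 ~ N(1−pb, σ), X2 ~ N(1+pb, σ)); the observable is
r = max/min ≥ 1.  σ is the same in both branches.  Non-positive
Gaussian draws are rejected and redrawn — intensities are physically
positive, and at σ ≈ 0.09 around means ≥ 0.77 a non-positive draw is an
~8.5σ event, so the redraw has no measurable effect on the law.

**Summary statistics.**  mean; CV = sample sd (n−1)/mean; skewness =
plain third standardized sample moment (the bias-adjusted variant is an
option; at n = 5000 the difference is ~0.03%).  Constant cohorts report
CV = 0 and skewness = 0 by convention.  Bootstrap CIs are percentile
intervals, B = 2000 by default; at n = 55 cells the mean-CI half-width
is ≈ 0.08, matching the Monte-Carlo sampling half-width of the mean
(1.96 × SE ≈ 0.083 by direct simulation).

**Moment matching.**  The estimator minimizes
Σ_j ((m_sim_j − m_obs_j)/w_j)² with weights w = (0.08, 0.03, 0.45) —
the bootstrap-CI half-widths of the observed moments — which puts the
three moments on comparable scales.  Each evaluation simulates 5,000
cells under common random numbers (CRN), making the objective a
deterministic function of (ps, σ, pb); search is a 9×9×9 grid over
[0,1]×[0,0.3]×[0,0.7] followed by Nelder-Mead.  Because the
moment-to-parameter inverse Jacobian is ill-conditioned at this cohort
size, a single CRN stream can place the exact root of its realized
objective far from the population root; the default fit therefore
repeats the search on three independent CRN streams and reports the
component-wise median.  Reported moments are re-simulated at a fresh
seed.  Degenerate targets (CV = 0) leave ps unidentifiable and are
flagged, as are infeasible targets (mean < 1).

**A note on inverting the published target moments.**  Self-consistent
recovery is accurate: targets simulated at known parameters are
recovered with median absolute errors ≈ 0.01 (ps), 0.002 (pb), 0.001
(σ) over seeded runs.  Feeding the rounded literature target moments
(1.4, 0.21, 0.58) to the estimator, however, returns
(ps, σ, pb) ≈ (0.38, 0.093, 0.217) rather than the published
(0.45, 0.09, 0.23): at two million simulated cells the published
parameters produce moments (1.391, 0.224, 0.621), so the published fit
reproduces those targets only to within their 95% CIs, not exactly, and
the exact least-squares inversion lands at a slightly smaller ps.  Both
parameter sets are statistically indistinguishable given n = 55 cells;
the package reports the exact minimizer and leaves the corresponding
ps check in the acceptance suite failing rather than widening it.

## Quantification operators

* `integrated_signal` — Σ over ROI voxels of (raw − background), summed
  across z; background is a scalar estimated upstream (mean of a
  background ROI), and negative per-voxel differences are kept so the
  total equals the difference of summed gray values.
* `chromatid_asymmetry` — max/min of two integrated signals; default
  threshold 1.5 (configurable, recorded in every output) chosen to
  separate the ~1.1 and ~1.6 ratio clusters of the fitted mixture; no
  published cut exists.
* `classify_division_angle` — half-open bins [0,30) parallel,
  [30,60) intermediate, [60,90] perpendicular; the published ranges
  overlap at 30° and 60°, so a deterministic convention is imposed.
* `colocalization` — Spearman rank correlation with midrank ties
  (Pearson available as an option; published descriptions of the
  colocalization index mention both), invariant to monotone intensity
  transforms.

## Synthetic-data generators

All generators are pure functions of (config, seed) with ground-truth
sidecars.  The EdU generator draws Binomial(n_cells, H2(t)) counts per
day — it emulates per-animal sampling noise, not section-to-section
variance or segmentation error, so passing recovery tests bound only
counting noise, not those systematic effects.  The telophase-cohort
generator uses a one-factor latent structure (shared division mode and
asymmetry direction per cell; each marker follows the shared direction
with probability `coupling`, else flips independently, plus
marker-specific Gaussian noise).  This is a modeling convenience
reproducing the strong positive cross-marker ratio correlations
(default Pol II coupling 0.994 was calibrated once by bisection at
n = 1e5 to give a signed-log-ratio correlation ≈ 0.868 versus p63); it
is not a mechanistic model of chromatid geometry.  Cohort-size defaults
mirror the study: 55 cells for experiment-sized fixtures, 5,000 for
model-sized.  The z-stack generator places Gaussian blobs on a constant
background with optional read noise; it makes no attempt at PSF,
bleed-through or other microscope optics.  The pair-fate generator's
default table is the published 48-pair composition (22 + 11 symmetric,
15 cross-fate); the split of the 15 asymmetric pairs across non-HBC
fates is not published and does not affect the asymmetric percentage.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5,000-cell
cohorts (10 seeds where averaged), 9³ grid + Nelder-Mead with 3 CRN
restarts per moment-matching fit, 7-point EdU time courses at 200
cells/day (50 seeds for the noisy-recovery bound), RK4 oracle at
1e-4-day steps over [τ, 14] days.

## Known limitations

* ps is weakly identified from (mean, CV, skewness) at realistic cohort
  sizes; its estimate inherits the full conditioning of the inverse
  problem (see the inversion note above).
* The delay is a hard hold, not a distributed lag; the model has a
  single differentiated pool and no spatial structure.
* Whether the basal pool should be normalized to 1 or to an absolute
  HBC count is unobservable from fraction data; the package normalizes
  to 1.
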