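# hbcregen

Models of olfactory horizontal basal cell (HBC) regeneration and
asymmetric cell division, for quantitative biologists studying how a
quiescent stem-cell pool re-enters the cell cycle after tissue injury
and how fate determinants are partitioned at mitosis.

The package implements two fitted models plus the quantification
operators and synthetic-data generators needed to exercise them end to
end without any experimental data:

**1. A delayed, feedback-regulated cell-cycle ODE.**  H1, H2, H3 are
the fractions of HBCs in G1, S and G2/M; D is the abundance of the
differentiated cells they produce:

```
dH1/dt = -k1·H1 + k3·H3        k1 = kmax / (1 + (D/K)^h)
dH2/dt =  k1·H1 - k2·H2
dH3/dt =  k2·H2 - k3·H3
dD/dt  =  k3·H3 - γ·D
```

The Hill feedback shuts HBC proliferation back down as the
differentiated pool rebuilds; an activation delay τ holds everything at
basal values just after injury.  k2 = 1.33/day and k3 = 6/day are fixed
by measured S (~18 h) and G2/M (4 h) phase durations; the free
parameters (kmax, τ, h, K, γ) are estimated by least squares against
EdU-labeling time courses (`RegenerationModel.fit()`).

**2. A stochastic mixture model of sister-chromatid RNA Pol II
partitioning.**  A telophase cell divides symmetrically with
probability ps (both chromatid intensities ~ N(1, σ)) or asymmetrically
with probability 1−ps (N(1−pb, σ) and N(1+pb, σ)).  The observable is
the per-cell ratio r = max(X1,X2)/min(X1,X2) ≥ 1, summarized by its
mean, CV and skewness with percentile-bootstrap CIs.  (ps, σ, pb) are
estimated by simulation-based moment matching with common random
numbers (`PartitionMomentModel.fit()`); the implied binding-affinity
fold change is (1+pb)/(1−pb).

Supporting modules: `quantify` (background-subtracted 3D integrated
intensity, asymmetry calls, division-angle classes, Spearman
colocalization) and `synthetic` (seeded generators with ground-truth
sidecars for every stage).

## Worked example

```python
import numpy as np
import hbcregen as h

# post-injury regeneration dynamics at the fitted constants
p = h.CellCycleParams()              # kmax=2.27, tau=0.8, h=2, K=0.4, gamma=0.06
traj = h.simulate(p, h.basal_state(0.065, p), np.array([0., 1, 2, 3, 5, 7, 14]))
print(traj.to_frame().round(4))

# sister-chromatid ratio cohort at the fitted mixture parameters
cohort = h.simulate_cohort(h.PartitionParams(ps=0.45, sigma=0.09, pb=0.23),
                           5000, seed=0)
print(h.bootstrap_ci(cohort, B=2000, seed=0))

# invert observed moments back to mixture parameters
res = h.PartitionMomentModel((1.4, 0.21, 0.58), n_sim=5000).fit(seed=0)
print(res.summary())
```

The trajectory shows the S-phase fraction H2 rising from its 6.5% basal
value after the τ = 0.8-day delay, peaking near day 1–2 (H2 ≈ 0.42 at
day 2) and relaxing toward baseline by day 14 (H2 ≈ 0.08) as the
differentiated pool D builds up and throttles k1.  The simulated cohort
reproduces the observed ratio statistics — it prints
`mean=1.387 CI=(1.379,1.396)`, `cv=0.225`, `skew=0.672` — and the
moment-matching fit reports, for targets (1.4, 0.21, 0.58):

```
  ps (P symmetric division)      0.370
  sigma (technical noise sd)     0.094
  pb (binding bias)              0.215
  P asymmetric = 1 - ps          0.630
  affinity ratio (1+pb)/(1-pb)   1.546
```

i.e. roughly 40% symmetric divisions, ~9% technical noise, and a
~1.5–1.6-fold binding-affinity difference between sister chromatids.
See `docs/methods.md` for why the exact inversion of those targets sits
a little below ps = 0.45.

A CLI mirrors the library (`hbcregen simulate-ode`, `fit-ode`,
`simulate-acd`, `fit-acd`, `summarize`, `quantify`, `coloc`,
`synth-edu`, `synth-cohort`, `synth-pairs`, `synth-stack`); every run
writes a JSON manifest with the seed and config hash.

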