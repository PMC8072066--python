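# Methods

## Model

The hematopoietic stem/progenitor hierarchy is modeled as a linear chain of
K = 4 compartments — HSC-U, HSC-D, ST-HSC, MPP — where the first two are
hidden inside the flow-cytometric HSC gate (LSK CD150⁺ CD48⁻).  Each
compartment carries a differentiation rate α_i (per day, flux into the next
compartment), a net proliferation rate β_i = λ_i − δ_i, and the derived
inverse residence time κ_i = α_i − β_i.  Expected sizes and labeled counts
both follow the linear cascade

    dx_1/dt = −κ₁ x₁,    dx_i/dt = α_{i−1} x_{i−1} − κ_i x_i,

and labeled frequencies f_i = l_i/n_i follow the equivalent nonlinear form
df_i/dt = α_{i−1}(n_{i−1}/n_i)(f_{i−1} − f_i), df₁/dt = 0.  Key model
assumptions: rates are constant over the analysis window (hence the 40-week
cap, excluding aging-related drift); labeled and unlabeled cells behave
identically; the chain is strictly linear (no branching, no backflow); sizes
and counts are deterministic expectations (no demographic stochasticity).

The observable HSC gate is always the aggregate of the two hidden pools:
count n_U + n_D and frequency (f_U n_U + f_D n_D)/(n_U + n_D).  Model-internal
HSC-U/HSC-D series are exposed but never compared to data directly.

The classical homogeneous steady-state model (three observed compartments,
constant sizes) is included as the special case df_i/dt = κ_i(f_{i−1} − f_i);
with only HSCs initially labeled its HSC-normalized downstream frequencies
relax to exactly 1, which is the behavior that real *Fgd5*-style datasets
(plateau ≈ 0.7) contradict and that motivates the hidden-subcompartment
model.

## Solvers and numerics

- Numerical integration uses a stiff-capable solver (LSODA) at rtol 1e−9 /
  atol 1e−12 with dense output on the observation grid, because κ values can
  span orders of magnitude.
- The linear cascades also have an exact sum-of-exponentials solution for
  pairwise-distinct κ (coefficients by the iterated-convolution recurrence
  C[i,j] = α_{i−1} C[i−1,j]/(κ_i − κ_j)).  This closed form is the
  verification oracle for every numerical solver and the fast evaluation
  path inside inference (where n is never small, l/n is numerically safe).
  A degenerate spectrum is resolved by perturbing colliding κ's by 1e−9 with
  a warning; a strict mode raises instead.
- Frequencies from the direct ODE are preferred for trajectory output (safe
  when n is small); l/n is retained as a cross-check, and the two agree to
  ≤1e−8 in tests.
- Frequency trajectories are validated to stay in [0, 1] to 1e−6 solver
  tolerance; a non-positive compartment size aborts frequency evaluation
  with an error naming the compartment and time.
- κ may be negative for the most immature compartment only (the HSC-U pool
  expands slowly over the window); downstream κ are kept positive by the
  default parameter transforms, switchable via the spec.

## Data pipeline

Input is a tidy per-mouse table (mouse, dataset, days since induction,
compartment, labeled frequency, optional count).  Preprocessing follows the
conventions of the comparable published time courses: measurement times are
shifted so t = 0 is the first effective post-tamoxifen measurement (offset
2 days by default; 1 day for sparse Krt18-style designs); the window is
capped at 280 days inclusive; observations are pooled into bins (the dense
Tie2-style course uses eight fixed intervals 0–20 … 188–208 days, chosen to
match the eight distinct Fgd5 time points); each bin's representative time
is the mean of its member observation times (midpoint selectable).  The
measurement error of a bin mean is a pooled-variance SEM: within-bin
variances are pooled per observable stream — per (compartment, quantity),
across bins and, by default, across datasets — and SEM = √(s²_pooled/n_bin).
Pooling per stream (rather than one variance for everything) is adopted
because counts and frequencies live on incommensurable scales; per-dataset
pooling is available as an option.

HSC normalization of downstream frequencies is done at the bin level:
normalized mean = (bin-mean f_comp)/(bin-mean f_HSC), with the SEM from
error propagation of the two means (noise in different flow gates treated as
independent).  Normalizing bin means rather than averaging per-mouse ratios
avoids the upward Jensen bias (≈ CV² of the per-mouse HSC frequency, several
percent for rare gates) that per-mouse ratios would carry into the fit.  A
per-mouse normalization column is still available for exploratory use.

## Inference

All datasets share one kinetics block (α₁..α₃, κ₁..κ₄, n₀) — the terminal
compartment's α is not separately identifiable from these observables and
only enters through κ₄ — plus per-dataset initial labeling f0 for the four
compartments (19 free parameters for a two-dataset fit).  The objective is
the weighted SSR over six streams per dataset: HSC aggregate frequency,
HSC-normalized ST-HSC and MPP frequencies, and the three observed counts,
each on its natural scale weighted by its pooled SEM.  Positive rates and
counts are optimized on the log scale, frequencies on the logit scale, κ₁ on
the natural scale; box bounds on the transformed scale (rates ≤ ~20/day,
n₀ ∈ [10, 1e8], f0 ∈ [1e−6, 1−1e−3]) keep the optimizer off degenerate
ridges.  An equivalent β-parametrization (with the terminal α fixed) is
provided and yields the same optimum, as tested.

Optimization is multi-start trust-region least squares: Latin-hypercube
starts on the transformed scale (seed-controlled), plus the spec's current
values and a data-informed heuristic start (initial sizes from first-bin
counts with the HSC gate split 1:5 upstream:downstream, initial labelings
spread around the first-bin HSC frequency).  Non-evaluable parameter points
contribute a large flagged penalty per residual rather than failing
silently.

Uncertainty uses profile likelihood with Δχ² = 3.84 (χ²₁, 95%): each
parameter is walked on its transformed scale with an adaptive step,
re-optimizing all others warm-started from the previous point; the crossing
is bracketed, refined by four bisection steps, and interpolated; a side that
never crosses within the configured span is reported as unbounded.
Prediction-profile bands re-use the same machinery by pinning the model
prediction with a stiff pseudo-observation and walking the target value; a
validation-style variant widens the band by ±1.96 SEM for comparison with
new bin means.  Driver specificity is reported as the ratio f0_U/f0_D per
dataset with a conservative interval (lower(f0_U)/upper(f0_D), and the
pairwise ratio of ratios between drivers).

## Synthetic cohorts

The generator emulates the structure of the three published cohorts:
cross-sectional designs (each mouse measured once), ~8 time points within 40
weeks, unequal mice per time point (Tie2-like bins carry 41, 61, 21, 8, 39,
34, 21, 17 mice; Fgd5-like, 7 per point; Krt18-like, 3 per point over six
points), and driver-specific initial labeling with HSC-U:HSC-D ratios 21:1,
4:1 and 30:1.  Reference kinetics are chosen once to reflect the consensus
picture of unperturbed adult hematopoiesis: HSC-U differentiates ~1 per 50
cell-weeks and slowly expands (κ₁ = −0.002/day); HSC-D differentiates ~once
per cell-week; ST-HSC turns over in weeks; the MPP pool is large and almost
self-renewing (κ₄ = 0.02/day); initial sizes (2e3, 1.2e4, 5e4, 2e5) keep the
upstream pool ≥5× smaller than HSC-D and sizes drifting by less than ~2×
over the window.  Death rates are configuration inputs; the default split
keeps all λ positive.

Measurement noise is an explicit stand-in for unpublished per-mouse error
structure: observed frequency is a binomial draw of labeled cells among C
sampled cells (C = 200 for the rare HSC and ST-HSC gates, 1000 for MPP) and
observed count is the expectation times mean-one lognormal noise (log-SD
0.2).  What passing recovery tests therefore show is that the pipeline and
estimator are correct and approximately calibrated *under this noise model*;
they do not certify calibration under real flow-cytometry error, which may
include gating drift, batch effects and inter-mouse biological variance that
the generator does not emulate.

A deliberate feature inherited from the pooled-variance convention: the
binomial variance f(1−f)/C drifts with f along the time course, while the
pooled SEM assigns one variance per stream.  Late-time bins are therefore
mildly over-weighted, and profile CIs for the most weakly identified
parameter (κ of HSC-D, half-life far beyond the window) empirically cover
the truth in a bit under 90% of replicates rather than the nominal 95% —
the price of the pooled-variance convention, not an estimator defect.

## Leukemogenesis

A mutation in compartment s multiplies λ_i by a factor x ≥ 1 for i ≥ s, so
the mutant inverse residence times are κ_i − (x−1)λ_i; mutant counts follow
the cascade seeded with one founder cell (deterministic continuum treatment;
stochastic extinction of small clones is out of scope).  The readout
p(t) = m₄/n₄ uses the wild-type MPP size in the denominator, taken literally
from the model definition (so expanding clones can exceed 1); a
bounded-fraction variant m₄/(n₄+m₄) is provided.  Persistence ("immortal"
MPP representation) is decided by the dominant mutant eigenvalue:
min_{i≥s} κ_i^mut(x) ≤ 0, implemented both as bisection to 1e−6 and as the
closed form x* = min_{i≥s} (α_i+δ_i)/λ_i (clamped at 1); long-horizon
simulation of sub- and supra-threshold scenarios cross-validates the
criterion.  The threshold is monotone along the hierarchy by a set-inclusion
argument, matching the qualitative origin-dependence of clonal expansion.
The published numeric thresholds depend on unpublished death-rate estimates
and are not reproduced; thresholds here carry their parameter provenance.

## Problem sizes and defaults used in the shipped studies

Recovery studies use 50 replicates of the two-dataset design (8 bins each,
per-bin mice as above) with 8 optimizer starts per fit; the out-of-sample
check uses 20 independent Krt18-like cohorts against one joint fit; oracle
equivalences use 100 random instances.  These sizes give stable pass/fail
statistics while keeping the full suite comfortably runnable on a laptop.

## Known limitations

- No branching topologies, age-dependent rates, longitudinal (same-mouse)
  sampling designs, Bayesian posteriors, or model selection across
  alternative topologies.
- The α of the terminal compartment is not estimable from these observables;
  it is a fixed configuration value wherever a β-parametrization needs it.
- Profile-CI calibration is approximate under the pooled-variance weighting
  (see above); prediction bands use the pointwise χ²₁ threshold.
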