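# Methods

## Scope and data model

`bspm` performs pointwise ("mass-univariate") inference on registered 1D
trajectories: a `TrajectorySet` is a J×Q matrix (J trials, Q time nodes,
conventionally Q = 101 spanning 0–100% of a movement cycle). Two designs
are supported: paired (J pairs, ν = J−1, effective n = J) and two-sample
(pooled variance, ν = n₁+n₂−2, effective n = n₁n₂/(n₁+n₂)). Nodes are
0-based internally; all reports are 1-based inclusive node ranges plus
percent of movement time `100·(node−1)/(Q−1)`.

Zero-variance nodes: a zero nodewise variance with a zero mean difference
(identical inputs) yields t = 0, the continuous limit; zero variance with
a nonzero difference raises a degenerate-node error naming the node.

## JZS Bayes factors

Hypotheses are parameterised by the standardised effect δ = (μ₁−μ₂)/σ with
the default Cauchy(r) prior (half its mass in [−r, r]; named scales
medium √2/2, wide 1, ultrawide √2). Because everything is computed from
(t, ν, effective n), the Bayes factor is invariant to the measurement
units.

**Point null.** BF₁₀ is evaluated by adaptive quadrature over the JZS
mixing variable g (δ|g ~ N(0, g r²), g ~ InverseGamma(½, ½)), with the
change of variables u = g/(1+g) mapping (0, ∞) to (0, 1). The integrand is
rescaled by its maximum on a coarse scan so the quadrature operates on an
overflow-free ratio; the quadrature tolerance is 1e−8 absolute / 1e−10
relative on that scale and the routine's absolute-error bound is reported.
One-sided priors (Cauchy truncated to a half-line, doubled density) are
integrated directly over δ against the noncentral-t likelihood with
noncentrality δ√n.

**Interval null.** H₀ and H₁ are the *same* parent Cauchy(r) truncated to
[−c, c] and its complement (default c = 0.2, the conventional bound of a
small effect). The Bayes factor is the posterior odds of the complement
over the interval divided by the prior odds:
`BF₁₀ = [P(δ∉[−c,c]|y)/P(δ∉[−c,c])] / [P(δ∈[−c,c]|y)/P(δ∈[−c,c])]`.
Prior interval masses are closed-form (arctangent); the posterior interval
mass is a 257-point Gauss–Legendre integral of the noncentral-t × Cauchy
density on [−c, c], normalised through the point-null marginal
(m₁ = m₀·BF₁₀, a Savage–Dickey-style identity). As c → 0 this converges to
the point-null BF; as a cross-check, reconstructing it from the gridded δ
posterior agrees to ~1e−4.

`delta_posterior` returns that δ posterior on a 20001-point grid centred on
the sample effect t/√n with half-width max(10, 10|t|/√n) prior-scale
units; tail truncation is negligible (< 1e−8) for ordinary inputs and the
density integrates to 1 within 1e−6.

Numerical guards: Bayes factors are carried in log space and capped at
exp(±700) with a `capped` flag and warning; a numerically degenerate
posterior interval mass (≤ 1e−300) also produces a capped, flagged result.
scipy's noncentral-t density can overflow internally in ultra-deep tails
(opposite signs of t and the noncentrality); those evaluations are treated
as −∞ log-density, which only affects regions of negligible mass.

**Posterior probability maps.** Each node's BF is converted through
`posterior odds = BF₁₀ × prior odds` (prior odds default 1). The map holds
PP, PEP = 1 − PP and q-values for both hypotheses. q-values are computed
per hypothesis (from pep_h1 = PP(H₀) and pep_h0 = PP(H₁) separately):
nodes are ranked by PEP ascending and q at rank k is the mean of the k
smallest PEPs, mapped back to node order; tied PEPs share the cumulative
mean at their last tied rank, making the result independent of sort order.
No further monotonicity adjustment (step-up re-sorting) is applied — the
q-value is defined purely as the cumulative mean. Clusters are maximal
runs with PP ≥ 0.95 (conservative rule) or q ≤ 0.05; thresholds are
inclusive. Since a node enters a PP cluster only with PEP ≤ 0.05 and its
q is a mean of PEPs no larger than its own, every PP-rule cluster is
contained in a q-rule cluster; the q rule additionally reports the largest
PEP it admitted. With the thresholds equal (0.95/0.05) no new clusters can
appear under the q rule — existing ones broaden or merge.

A caution on prior-scale intuition: wider priors penalise the alternative
where |t| is small (broadening H₀ clusters), but at the large |t| needed
to reach PP(H₁) ≥ 0.95 with few trials the ordering reverses — wide priors
put more mass on large effects, so the |t| needed for BF₁₀ = 19 *shrinks*
slightly with r (e.g. 4.25/4.10/3.99 for medium/wide/ultrawide at ν = 10,
effective n = 3). Claims that wider priors are uniformly more conservative
hold only in the small-|t| regime.

## Classical SPM{t} and random field theory

Residual smoothness is estimated from the nodewise-centred residuals
(paired: centred differences; two-sample: both groups centred, stacked):
columns are normalised to unit norm, discrete gradients are taken along
the node axis (central differences inside, one-sided at the ends), and
FWHM = √(4 ln 2 / mean squared gradient), capped at 10·Q when gradients
vanish (flat fields). Identical inputs (all-zero residuals) are treated as
that flat-field limit inside `spm_t_test`; `estimate_fwhm` itself raises.

The critical threshold solves the 1D expected-Euler-characteristic
approximation `P(T_ν ≥ u) + R·(√(4 ln 2)/2π)(1+u²/ν)^(−(ν−1)/2) = α` by
monotone root finding, with resel count R = (Q−1)/FWHM. Two-tailed
inference applies α/2 per tail to |t|. Cluster extents are counted in
whole nodes and converted to resels — no sub-node interpolation of the
crossing points is performed, so cluster p-values may differ in the third
decimal from implementations that interpolate. The cluster p-value treats
the number of supra-threshold clusters as Poisson with mean
E[m] = R·EC-density(u) (doubled for two tails) and the extent as
exponential with mean E[N]/E[m], E[N] = R·P(T ≥ u):
`p = 1 − exp(−E[m]·exp(−k·E[m]/E[N]))`, strictly decreasing in the extent
k and approaching α as k → 0 at u = t*.

Degrees of freedom are classical (no smoothness-based correction), and
variance is assumed stationary along the field.

**Calibration.** Monte-Carlo checks (2000 replicates) put the field-wide
false-positive rate of the threshold at α = 0.05 within 0.05 ± 0.015 for
2×6 trials and FWHM ∈ {5, 10, 20} on Q = 101 nodes. The approximation is
known to run *conservative* at very small degrees of freedom: for paired
designs with n = 5 (ν = 4) the measured rate is ≈ 0.03–0.04. Power and
error-rate statements are therefore most trustworthy for ν ≳ 8, which
covers the sample sizes this kind of analysis is used with.

## Synthetic data

All generators are deterministic under a fixed seed and return valid
`TrajectorySet`s.

**Smooth unit fields** — white Gaussian noise convolved with a Gaussian
kernel of the requested FWHM (truncated at ±4σ), then rescaled nodewise by
the exact per-node variance of the truncated convolution, so *every* node
(including the field ends) has unit variance in expectation. "Unit
Gaussian" is thus interpreted as unit pointwise variance after smoothing.

**Two-local-max design** — group 1 is plain smooth unit fields; group 2
adds Gaussian-pulse mean offsets at two nodes (defaults: 2×6 trials,
Q = 101, bursts at nodes 25 and 75, burst FWHM 10). The default burst
amplitude of 3.0 (units of trajectory SD) is generator tuning, chosen so
that the classical SPM detects clusters near both bursts in a majority of
random draws at this sample size (~93% detect at least one cluster, ~65%
both), mirroring the canonical two-cluster demonstration result.

**Gait-like design** — a smooth periodic knee-flexion baseline (a small
stance-phase bump of ~15° near 15% of the cycle plus a ~60° swing-phase
peak near 72%) for both "legs"; the second leg is offset by a Gaussian
pulse of height `asymmetry_deg` centred at 76% (FWHM 12 nodes), and each
cycle adds smooth noise scaled by `within_sd`. The default
within_sd = 2.4° with 20-node smoothness represents typical cycle-to-cycle
kinematic variability; under these conditions a 2° minimal-relevant
asymmetry reaches 80% omnibus power at roughly 50 cycles, the planning
regime this design is meant to emulate.

What the generators do *not* emulate: between-subject variance structure,
skewed or heteroscedastic noise, registration (time-warping) error,
autocorrelated cycle-to-cycle drift, and non-stationary smoothness along
the cycle. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated stationary Gaussian conditions, not
robustness of the method on arbitrary real data.

## Continuum power analysis

`continuum_power` takes a null and an alternative `ContinuumModel`
(baseline curve + effect curve + noise spec). For each candidate n it
simulates paired datasets — condition A from the null model, condition B
from the alternative — runs the classical paired SPM{t} at α, and reports
omnibus power: the fraction of simulations with at least one
supra-threshold cluster anywhere on the continuum. With the alternative
equal to the null this estimates the field-wide false-positive rate
(≈ α for ν ≳ 8, see above). Default problem sizes (500–1000 iterations,
n grids of ~10 values) keep a full curve under half a minute; power values
carry the usual binomial Monte-Carlo error √(p(1−p)/iterations).

## Analysis runs and I/O

Trajectory files are plain CSV/TSV trial matrices (rows = trials,
columns = nodes, optional header row, auto-detected delimiter); parse
errors name the offending row and column, and writing uses full float
precision so a write–read round trip is bit-exact. `run_analysis` executes
the Bayesian and classical analyses together and writes cluster tables
with a fixed schema (dataset, design, null_type, r_label, hypothesis,
rule, start_node, end_node, start_pct, end_pct, extremum [, p_value]) plus
a JSON manifest (inputs, full configuration, seed, package versions)
sufficient to reproduce the run exactly; plots are optional and never part
of any computed result. The CLI is a thin wrapper: flags override YAML
config values, named prior scales resolve to their numeric values, and
invalid settings fail with a usage error before any computation.
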