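# Methods

This note records the models, conventions, numerical choices and known
limitations behind `conncrit`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Thresholded networks and graph measures

A connectivity matrix holds correlation weights `w_ij ∈ (−1, 1)`,
symmetric with zero diagonal; matrices are validated once on ingestion
(symmetry within 1e-9, then exact symmetrisation by averaging; diagonal
zeroed). An edge exists at threshold `r_c` iff `|w_ij| > r_c`, strictly:
ties at the threshold are excluded. Degree counts supra-threshold
neighbours; strength sums their `|w_ij|`, so `s_i ≥ r_c · k_i` holds
entry-wise.

Characteristic path length averages hop counts over ordered pairs with the
substitution `L_ij := N` for unreachable pairs, which makes `⟨L⟩` finite
and strongly sensitive to fragmentation. Global efficiency uses the
standard convention `1/L_ij := 0` for unreachable pairs; since the
substitution variant (`1/N`) is also defensible, both are exposed through
the `unreachable` flag of `global_efficiency`/`metric_sweep`, with `"zero"`
the default. Transitivity is the global triangle density
`3·triangles / connected triples`, defined as 0 when no triples exist.
Cost is the edge count; in a sweep the per-threshold *mean* cost is
additionally normalised by its maximum over the sweep, so `E/Cost` is
comparable across thresholds. Aggregation across a collection is always
per-matrix-first: each matrix is measured alone, then means and standard
deviations are taken across matrices.

Shortest paths and connected components run on `scipy.sparse.csgraph`;
transitivity uses the `trace(A³)` identity. The test suite cross-checks all
three against brute-force oracles (triple enumeration, Floyd–Warshall) to
1e-12 and against networkx, keeping implementation and oracle independent.

## Distribution models

Three continuous families model positive degree/strength samples (degrees
are treated as continuous too, so one likelihood machinery serves both):

* restricted (bounded) power law
  `P(x) = ((γ+1)/(x_max−x_min)) ((x_max−x)/(x_max−x_min))^γ`,
  `x ∈ [x_min, x_max]`, `γ > −1`. Closed forms:
  `F(x) = 1 − ((x_max−x)/(x_max−x_min))^{γ+1}`,
  `F⁻¹(u) = x_max − (x_max−x_min)(1−u)^{1/(γ+1)}`,
  `E[X] = x_max − (x_max−x_min)(γ+1)/(γ+2)`.
* exponentially truncated power law `P(x) ∝ x^{α−1} e^{−x/x_c}` on
  `[x_min, ∞)`. The decaying exponential is implemented; a growing
  exponential is not normalisable on an unbounded support. Negative `α` is
  admitted: it is the regime in which the family mimics a decaying pure
  power law (`α = 1 − a` for tail index `a`) when `x_c` is large, and
  excluding it would break that limit.
* pure power law `P(x) = ((α−1)/x_min)(x/x_min)^{−α}`, `α > 1`.

The truncated normalising constant is `x_c^α Γ(α, x_min/x_c)` (upper
incomplete gamma). For `α > 0` it is evaluated through
`scipy.special.gammaincc` in log space, with a three-term asymptotic
fallback when the regularised value underflows. For `α ≤ 0` (outside
scipy's domain) the integral is split at `t = 1`: the tail is adaptive
quadrature, and the near-origin part — steep when `x_min/x_c` is small — is
integrated exactly term by term via the alternating series of `e^{−t}`
(40 terms, far beyond double precision). This split matters: naive
quadrature over the whole range silently loses the spike near the origin
and can corrupt likelihoods by orders of magnitude.

Sampling is inverse-CDF throughout. The restricted and pure power laws use
their closed-form inverses; the truncated family inverts through the
conditioned-gamma survival function (`gamma.isf`) for `α > 0` and by
bracketed root-finding (`brentq`, xtol 1e-10) for `α ≤ 0`. Samplers are
checked against the analytic CDFs by Kolmogorov–Smirnov at the 1% critical
value `1.63/√n`.

## Fitting and model selection

All fits maximise the log-likelihood `Σ log P(x_i | θ)`; raw likelihood
products would underflow for realistic sample sizes. In every model the
lower support bound is plugged in as `x_min = min(sample)` and not counted
as a parameter, giving `K = 1` (power law: `α`) and `K = 2` (truncated:
`α, x_c`; restricted: `γ, x_max`). Models are ranked by
`AICc = −2 log L + 2K + 2K(K+1)/(N−K−1)`; ties break toward fewer
parameters, then the fixed order (powerlaw, truncated, restricted). Samples
need at least 5 positive values; zero entries (disconnected nodes) are
dropped first, and matrices that fall below the floor are skipped and
counted, never silently dropped.

* Power law: closed-form MLE `α = 1 + N / Σ log(x_i/x_min)`.
* Truncated: L-BFGS-B over `(α, log x_c)` with bounds `α ∈ [−5, 50]` and
  five restarts jittered around moment-matched gamma initial values
  (`α₀ = m²/v`, `x_c₀ = v/m`). An all-equal sample is rejected as
  degenerate (the MLE collapses to a spike).
* Restricted: for fixed `x_max` the exponent has the closed-form profile
  `γ + 1 = 1 / mean(log((x_max−x_min)/(x_max−x_i)))`, so the problem
  reduces to one dimension: a 120-point log-spaced scan of
  `x_max − max(sample)` over `(max·1e−6, 99·max)` followed by bounded local
  refinement. The lower margin `max(sample)·(1+1e−6)` is not cosmetic: it
  regularises the classic unbounded-likelihood pathology of endpoint
  estimation (`x_max → max(sample)` with `γ → −1` sends the likelihood to
  infinity); for `N ≳ 30` the margin keeps that divergence numerically out
  of reach. Hitting the upper box bound (`100·max`) raises a
  flat-likelihood warning — it signals data with no detectable ceiling.

A structural caveat verified by the tests: the power law is nested in the
truncated family (`x_c → ∞`), so on power-law data the truncated fit's raw
likelihood always ties or wins; only the AICc penalty recovers the power
law, and at `N = 1000` it does so in roughly 85% of replicates — the
theoretical rate for a one-parameter nesting, not an implementation defect.
The likelihood-dominance checks therefore compare raw likelihoods only
between non-nested pairs.

## Subsampling

Noise-reduction subsampling sorts the `N` raw values ascending by absolute
value (stable sort) and extracts the `n` order statistics at ranks
`round_half_up(d(2i−1)/2)`, `d = N/n`, clamped to `[1, N]` — cumulative
positions `(2i−1)/2n`, i.e. 0.05 … 0.95 for `n = 10`, and the identity for
`n = N`. Half-up rounding was chosen precisely so that `n = N` is the
identity. The scheme's value lies in what it never selects: the extreme
order statistics, which are the points additive noise distorts most.

## Synthetic generator

The generator emulates what the analysis assumes about real connectome
corpora: per node `i` a latent propensity `f_i ∈ [0,1]` (rescaled from a
configurable law; default the restricted law with `γ = 2.22`, support
`[0.546, 33.5]` — the strength-scale reference fit), raw weights
`u_ij = f_i f_j + ε_ij` with `ε ~ N(0, noise_sd²)` (default 0.05), a sign
flip on a fraction (default 0.2) of entries so that `|w|`-thresholding is
genuinely exercised, and the saturating odd map
`w = clip_limit · tanh(map_gain · u)` (defaults 0.999 and 5.0). Per-matrix
streams derive from `(seed, matrix index)`, so collections are reproducible
and order-independent.

The map gain is the one deliberately calibrated constant: with unit gain
the default propensity law yields networks far sparser than real sweeps
(a handful of connected nodes at mid thresholds), leaving nothing for the
distribution analysis to see. Gain 5.0 keeps the synthetic networks densely
connected through the intermediate threshold range with a fragmentation
transition near `r_c ≈ 0.6–0.7` and an interior `E/Cost` peak — the regime
structure the sweep analysis is about. Under these defaults the full
downstream pipeline (threshold → strength → fit → AICc) re-identifies the
generating bounded law at mid thresholds, and at `noise_sd = 0.1` the
low-threshold regime becomes noise-dominated and flips to the truncated
model, with mid-quantile subsampling (n = 50) recovering the bounded one —
the qualitative three-phase pattern.

What the generator does **not** emulate: spatial embedding and distance-
dependent correlations, the empirical marginal weight distribution of real
fMRI matrices (unreported for the reference corpus; the product-plus-noise
law is a modelling choice validated only through downstream behaviour),
negative-correlation structure beyond random sign flips, and subject-level
covariates. Passing tests therefore demonstrate internal consistency of
the method chain, not fidelity to any particular dataset; reproducing
selection percentages reported for real multi-subject corpora is out of
scope.

## Cost-stability simulation

`simulate_strength_means` draws `n_nodes` strengths per replicate through a
model's inverse CDF and records replicate means; `delta_mean_strength`
compares their average with an empirical reference
(`Δ⟨s⟩ = ⟨s⟩_sim − ⟨s⟩_ref`). Desk-scale default is 200 replicates. One
subtlety the tests make explicit: on clean bounded samples both MLE fits
centre on the sample mean (the truncated/gamma family matches it exactly
through its sufficient statistics), so the bounded model's advantage is
*stability*, not bias — its replicate means have systematically smaller
spread (median spread ratio ≈ 1.1–1.2 at the reference parameters), and in
single-run simulations it lands closer to the empirical mean more often
than not. Restricted-model draws can never leave `[x_min, x_max]`, whereas
truncated draws exceed `x_min + 5 x_c` with positive probability.

## Pipeline and reports

`run_full_analysis` writes `metrics.csv` (per-threshold means/SDs plus
`ΔC = C(r_c) − C(r_c+step)`, normalised cost and `E/Cost`),
`selection.csv`/`.json` (selection ratios and mean-ΔAICc per threshold,
stat kind and subsample size), `ccdf.csv` (per matrix/threshold the
empirical complementary cumulative, `P_c(x) =` fraction of values `≥ x`,
the form plotted on log-log axes against fitted curves), `simulation.json`
(restricted/truncated fits at the middle comparison threshold, per-matrix
parameters averaged, simulated `⟨s⟩` vs the per-dataset-first empirical
mean) and `manifest.json` (seed, version, config hash). Reruns under the
same config and seed are byte-identical. Default grids: `r_c = 0.0–0.9`
step 0.1 for metrics, `0.2–0.7` step 0.1 for model comparison.

## Problem sizes

Desk-scale defaults keep every stage interactive: collections of 10–20
matrices of 60–177 regions, 100–200 Monte-Carlo replicates for selection
frequencies, `N = 5000` for parameter recovery, `10⁵` draws for sampler
checks. All are configurable; the estimators do not change with size.

## Known limitations

* Degrees are fitted with continuous likelihoods; for very sparse networks
  (degrees concentrated on a few small integers) a discrete treatment
  would be more faithful.
* `x_min` is plugged in from the sample minimum for all models rather than
  optimised (no Clauset-style tail selection), and no goodness-of-fit
  p-values are computed — selection is purely relative (AICc).
* The restricted-model `x_max` estimate is weakly identified when the true
  law has no ceiling; the flat-likelihood warning flags this but the fit is
  still returned.
* The truncated-family normalisation for `α ≤ 0` costs one quadrature per
  likelihood evaluation; fits in that regime are ~10× slower than for
  `α > 0`.
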