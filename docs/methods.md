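# Methods

## Model

For a focal taxon *j* observed in *N* hosts at ordinal time points, let
`y` stack the relative abundances at times `t = L+1 … T_i` over hosts
(`L = max(p, q)`). The model is a linear mixed model

```
y = X β + W̃ u + H r + ε,
u ~ N(0, σ²_u I),  r ~ N(0, σ²_r I),  ε ~ N(0, σ²_ε I),
```

where `X` holds an intercept and the focal taxon's own `p` raw lags, and
`W̃` holds the whole community's quantile-binned values at lags
`1 … q` (taxon-major column order). `H` is `W̃` with rows permuted
uniformly at random *within each host block*: it carries host identity
but no temporal ordering, and absorbs host effects that would otherwise
masquerade as temporal signal. Marginally,

```
y ~ N(X β, σ²_AR K1 + σ²_ind K2 + σ²_ε I),
K1 = W̃W̃'/c,  K2 = HH'/c,  σ²_AR = c σ²_u,  σ²_ind = c σ²_r,
```

with `c` the number of community columns (`q` lags × kinship taxa); the
normalization by `c` rather than the taxon count keeps `K1` on the same
scale for any `q`. `K1` is the *temporal kinship matrix* — the analogue
of a genetic relationship matrix, measuring how similar the recent
community history of two samples is.

**Time-explainability** is the variance share of the temporal kinship
component, `χ = σ²_AR / (σ²_AR + σ²_ind + σ²_ε)`. A taxon is called
*autoregressive* when its χ is significantly positive after
Benjamini–Hochberg adjustment (default α = 0.05).

Assumptions worth keeping in mind: sampling is treated as equally
spaced (time indices are ordinal; real calendar gaps are ignored); the
dynamics are time-homogeneous; relative abundances enter the response
untransformed; and after the presence screen, "relative abundance"
retains its whole-community denominator (screened rows are dropped
without re-closure, so the values the model sees do not depend on which
taxa were screened).

## Preprocessing

- **Closure**: counts are converted to proportions per sample; an
  all-zero sample is an error.
- **Presence screen**: a taxon is kept iff it is non-zero in ≥ 10% of
  all samples, pooled over hosts (inclusive threshold). Pooling matches
  the single shared kinship matrix; a per-host alternative is exposed in
  the API.
- **Binning**: per taxon, thresholds are the (0.25, 0.75) empirical
  quantiles (linear interpolation, pooled over hosts). Values strictly
  below the lower threshold map to 0, strictly above the upper to 2,
  else 1. With heavy zero inflation the lower threshold is often exactly
  0, so zeros legally land in the middle bin; the binning-sensitivity
  harness exercises alternative quantile pairs and rank-based quantile
  normalization. For out-of-sample prediction and model selection the
  thresholds are estimated on the training block only and applied to
  the full series, so no information flows from evaluation blocks into
  the coding; for cohort-level time-explainability (no held-out data)
  the thresholds are pooled.

## REML estimation

Variance components are estimated by restricted maximum likelihood
using average-information (AI) updates. Numerical choices:

- Correctness is defined by the dense restricted log-likelihood
  `-½(log|V| + log|X'V⁻¹X| + y'Py)`; the iterative fitter must maximize
  exactly this function (a dedicated test compares both paths, and a
  derivative-free direct maximization serves as an independent oracle).
- Both kinships are Gram matrices of known factors, so `V` acts as
  `σ²_ε I` on the orthogonal complement of the stacked factor span. One
  QR decomposition per fit reduces every per-iteration quantity
  (determinants, GLS solves, traces, the AI matrix) to dense algebra in
  that span — O(K³) per iteration for K factor columns instead of O(n³).
- The first step is an EM-REML update; later steps are AI updates with
  step-halving and an EM fallback whenever a proposal would decrease the
  likelihood or leave the feasible region.
- Components are constrained non-negative by clamping at a floor of
  `1e-6 · var(y)`. Components pinned at the floor with an outward
  gradient are removed from the AI solve (active set), which prevents a
  near-boundary component from distorting the step for the free ones.
  An unconstrained escape hatch exists (`constrain=False`).
- Convergence requires both `|Δ log-likelihood| < 1e-6` and a relative
  parameter change `< 1e-4`, within 100 iterations; non-convergence is
  flagged and downstream operations refuse unconverged fits.
- The covariance of the variance-component estimates is the inverse AI
  matrix at the optimum (symmetrized, negative eigenvalues truncated).

The 95% CI for χ comes from the delta method applied to that
covariance, clipped to [0, 1]. Significance of `σ²_AR > 0` uses the
restricted likelihood-ratio statistic against the null refit with the
AR component removed, referred to the boundary mixture
`½χ²₀ + ½χ²₁` (a non-positive statistic gives p = 1). This test is
conservative in small samples, which the null-calibration experiment
quantifies.

## Prediction (BLUP)

A held-out observation is predicted by conditional-normal (BLUP)
prediction: `ŷ = x'β̂ + c' Σ⁻¹ (y − Xβ̂)` with
`Σ = σ²_u W̃W̃' + σ²_r HH' + σ²_ε I` and `c` the covariance between the
new point and the training rows. The community part of `c` is
`σ²_u W̃ w_new`. The individual part is genuinely open: the scrambled
row a new sample would contribute to `H` is unknown. We replace it by
its conditional expectation given the block — the mean `H` row of the
target's host — giving `σ²_r H h̄_i` across *all* training rows (the
individual effect `r` is shared). Because both parts are inner products
against training factor rows, the implied joint covariance is positive
semidefinite and the conditional variance is always non-negative; an
ad-hoc alternative we tried first (block means of `K2` rows) does not
have this guarantee.

Sequential evaluation holds out only the target time: lags always come
from *observed* history, parameters are fitted once on the training
block, predictions are clipped below at 0, and accuracy is the squared
Pearson correlation between observed and predicted series (zero-variance
degenerate cases return 0 with a warning rather than NaN).

The species–species association matrix `U` collects each focal taxon's
BLUP of the community effects, `û = σ̂²_u W̃' Σ̂⁻¹ (y − Xβ̂)`, with lag
columns of the same taxon summed when q > 1; columns with `σ̂²_u = 0` or
an unconverged fit are zero and flagged.

## Model selection and baseline

Each host's series is split chronologically into train / validation /
test blocks (default thirds; floor allocation with remainders to the
earlier blocks, so T = 31 gives 11/10/10). The four candidate orders
(p, q) ∈ {(0,1), (1,1), (0,3), (1,3)} are fitted on the train block and
scored by one-step-ahead R² on validation; ties break toward smaller q,
then smaller p. The winner's test R² is reported from a single pass over
the test block. The AR(1) comparator is per-host ordinary least squares
of `y_t` on `[1, y_{t−1}]` over train+validation (it has no
hyperparameters to tune), with R² pooled over all hosts' test points.
Paired method comparisons use the Wilcoxon signed-rank test.

## Synthetic data

`simulate_lmm` draws from the model's own generative process: an
i.i.d. trinomial community coding (occupancies ¼, ½, ¼), Gaussian
effects, and variance scales `σ²_u = χ/c`, `σ²_r = φ/c`,
`σ²_ε = 1 − χ − φ` so that the focal taxon's true time-explainability
equals the requested χ. The effect vectors are drawn i.i.d. normal as
the model states, so the realized variance shares carry a
`χ²_c`-distributed norm fluctuation around the request; recovery
experiments therefore use a community of c = 100 columns, where that
fluctuation is small next to the estimator's own error and model-based
confidence intervals attain near-nominal coverage. One generator choice
matters a great deal: the per-host permutation stream is shared with
the design builder, so a refit at the recorded seed sees the generating
`H` (a correctly specified model); with an unrelated permutation,
`σ²_ind` is not identifiable from a single realization and leaks into
the residual.
The community carriers are continuous values drawn inside
well-separated ranges per bin, so the standard (0.25, 0.75) binning of
the emitted dataset reproduces the generating coding almost exactly.

`simulate_community` emulates a realistic cohort (defaults: 200 taxa,
70 time points, 10 hosts): latent log-abundances follow
`x_t = a + B(x_{t−1} − a) + ε` with intercepts `a ~ N(0, 1.5²)`, a
sparse stable interaction matrix `B` whose non-zero rows belong to a
planted autoregressive subset (self-dependence uniform on 0.5–0.9,
5% cross-effects, spectral radius rescaled below 1 if needed), softmax
closure, and zero inflation that zeroes the smallest 30% of each
sample's proportions before re-closure. Three parameterization details
keep the planted labels meaningful:

- dynamics act on deviations from the intercept, so strong
  self-dependence does not inflate a taxon's stationary mean by
  `1/(1−b)` and capture the whole softmax;
- innovation standard deviations scale with `sqrt(1 − b²)`, making the
  stationary latent variance homogeneous, so the presence screen treats
  planted and background taxa alike;
- the autoregressive and background blocks receive fixed total mass
  shares (the planted block's share equals its taxon fraction) and are
  closed separately. A single softmax over all taxa would push the
  planted block's dynamics into every taxon through the shared
  denominator, leaving no taxon truly non-autoregressive and making
  "specificity" ill-defined under closure.

A taxonomy is attached in which the planted taxa concentrate in two
orders, giving the order-label permutation test a planted signal.

What the simulators do **not** emulate: sequencing-depth noise and
library-size variation, calendar-time irregularity, overdispersed count
sampling, taxon correlations within the background block, and real
phylogenetic structure. Passing tests therefore demonstrate estimator
correctness and calibration under the stated generative assumptions,
not performance on any particular real cohort.

## Validation battery and problem sizes

The experiments behind `tests/test_acceptance.py` and
`scripts/acceptance.py` use these sizes, chosen to give stable
statistics while the whole battery runs on one CPU in minutes: 25
random instances (n ≤ 60) for REML–oracle agreement and 25 (n ≤ 40) for
BLUP–oracle agreement; 4 × 50 replicates at N = 20 hosts, T = 50 for χ
recovery; 200 null taxa at N = 10, T = 30 for calibration; one
200-taxon, 70-time-point, 10-host community for detection power;
20 replicates for the AR(1) nesting comparison. Detection sensitivity
and specificity are computed over taxa that pass the presence screen —
the pipeline never models the others.

## Known limitations

- The boundary LRT is conservative; at small n the raw false-positive
  rate is well below nominal, which costs a little power.
- Pooled binning for the cohort-level χ pipeline lets later samples
  influence the coding of earlier ones (flagged; prediction pipelines
  use train-only thresholds).
- The association matrix estimates m² effects from far fewer samples;
  individual entries are noisy and only aggregate structure (e.g. PCA)
  should be interpreted.
- `H` is one random permutation per design build; χ estimates therefore
  carry a small seed-dependent component through `K2`.
- Predictions are clipped below at 0 but not re-closed across taxa.
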