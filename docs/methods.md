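# Methods

## Model and estimator

The estimator targets mutual information between variables whose dependence
is carried by their copula — the joint distribution of marginal-CDF values.
Since MI is invariant to monotone transforms of each marginal, any marginal
can be replaced at will provided the empirical copula is preserved. The
package replaces each variable (each column of a multivariate variable,
independently) by the inverse standard-normal CDF of its ranks rescaled by
N+1, yielding exact standard-normal marginals on the fixed grid
Φ⁻¹(i/(N+1)), i = 1..N. Gaussian parametric formulas are then applied:

- entropy: H = (1/2 ln 2) · ln[(2πe)ᵏ |Σ|], evaluated via the Cholesky
  log-determinant;
- MI and CMI: entropy combinations H(X)+H(Y)−H(XY) and
  H(XZ)+H(YZ)−H(Z)−H(XYZ).

The implicit assumption is a Gaussian copula *linking* the variables (never
Gaussian marginals). Because the Gaussian copula maximizes entropy among
copulas with the same covariance, and MI is the negative copula entropy,
any violation of the assumption can only lower the estimate: the value is a
lower bound on the true MI. The practical consequences, verified in the
test suite, are:

- dependence invisible to ranks' second-order structure (e.g. y = |x| + ε)
  is reported as ≈ 0 bits;
- estimates are bit-exactly invariant to strictly monotone marginal
  transforms, and hence robust to outliers;
- for data with a genuinely Gaussian copula the estimate converges to the
  analytic value.

Two fully separated classes in the discrete–continuous estimator saturate
at −½·log₂(1−2/π) ≈ 0.73 bits rather than the 1-bit label entropy: pooled
rank normalization maps the classes onto the two halves of a standard
normal (truncated variance 1−2/π), and the Gaussian conditional fits
overestimate the class entropies. This is the lower-bound property at work,
not an implementation artifact.

Because the estimates are lower bounds, the data-processing inequality
constrains true MI but not the estimates: a derived channel (e.g. the
amplitude-normalized direction of a spectral vector) can legitimately score
*above* the full vector when the normalization makes the class-conditional
copula more Gaussian. Channel estimates should be read as "at least this
much information in this channel", not compared as a partition.

## Bias correction

The sample covariance log-determinant is biased; (N−1)·Σ̂ follows a Wishart
distribution, whose log-determinant expectation exceeds ln|Σ| by
Σᵢ ψ((N−i)/2) + k·ln(2/(N−1)) (ψ the digamma function). Subtracting that
quantity inside the entropy formula gives an estimate that is exactly
unbiased in the log-determinant term; a Monte-Carlo property test confirms
unbiasedness within three standard errors for k ∈ {1,2,4}, N ∈ {20,50,200}.
The correction requires N > k+1 and is *not* clipped at zero — corrected
null-level estimates legitimately fluctuate below zero.

Convention: bias correction defaults **on** for the effect-size estimators
(`gcmi_*`, higher-order quantities) and **off** inside permutation tests,
where only the ordering of observed vs permuted statistics matters and the
correction merely adds variance. All outputs are in bits (log base 2).

## Discrete–continuous estimator

I(X;Y) = H(X) − Σ_y P(y)·H(X|Y=y) with: ranks computed pooled over classes
(preserving the rank–class relationship); the unconditional entropy from a
Gaussian fit to the pooled normalized data (exactly standard normal by
construction, so the fit and the class mixture coincide); class-conditional
entropies from per-class Gaussian fits with per-class sample counts in the
bias correction; and empirical class priors. Classes need ≥ 3 samples
(> k+1 for correction). The group decomposition normalizes ranks per
participant, reports pooled MI, total CMI given participant identity
(computed as the participant-frequency-weighted within-participant MI), and
their difference as heterogeneity — total = pooled + heterogeneity holds
exactly by construction.

## Higher-order quantities

- Interaction information II = I(R1,R2;S) − I(R1;S) − I(R2;S); negative =
  redundancy, positive = synergy. Note redundant and synergistic
  contributions can cancel in the average; the package reports the net
  value and does not attempt a partial-information decomposition.
- Normalized redundancy = 100·(−II)/min{I(S;R1), I(S;R2), I(R1;R2)};
  synergistic cases are reported as 0% with a flag, a degenerate bound as
  NaN.
- Directed information at lag ℓ with embedding m conditions the target's
  present on m past samples of itself while testing m past samples of the
  source (default m = 1). Directed feature information subtracts the DI
  additionally conditioned on the stimulus at the *source* times t−ℓ: the
  feature content the source carried when the communicated activity left
  it. A constant stimulus returns exactly 0 by the algebraic identity.
- Novel information at time t is I(S; R_t | R_{t−1}); anchor time points
  supplied by the caller can be added to the conditioning set (the package
  does not choose anchors automatically).

Degenerate inputs: exactly duplicated columns (including monotone copies,
which normalize identically) are dropped from joint terms, realizing the
mathematical limits I(R,R;S) = I(R;S) and I(S;X|X) = 0 rather than failing
on singular covariances. Joint-term columns are assembled in a canonical
order so that II is bit-exactly symmetric in its response arguments.
Anything merely *nearly* collinear still raises, naming the offending
dimension.

## Binned reference estimators

Equipopulated quantization labels sample i with ⌊rank·nbins/N⌋ using
ordinal ranks (ties broken by original index), so bin counts never differ
by more than one and labels inherit monotone-transform invariance; a
warning flags ties straddling a bin boundary, where quantiles are
degenerate. Plug-in MI comes from the empirical contingency table; the
Miller–Madow correction subtracts the null expectation
(|R|−1)(|S|−1)/(2N ln 2) bits — the χ² null mean of the G statistic
G = 2N ln(2)·I on the MI scale, with the natural log in the denominator so
the term is in bits.

## Permutation inference

Mass-univariate maps are thresholded at the
⌈(1−α)(n_perm+1)⌉-th order statistic of the per-permutation grid maxima.
The +1 counts the observed (identity) permutation, matching the permutation
p-value convention p = (r+1)/(n_perm+1); under exchangeability this
guarantees FWER ≤ α (at 200 permutations and α = 0.01: 2/201 ≈ 0.00995),
whereas thresholding at ⌈(1−α)·n_perm⌉ is anticonservative at small
permutation counts (3/201 ≈ 0.0149). For autocorrelated series, blockwise
permutation reorders contiguous blocks (an incomplete trailing block is
kept as its own shorter block, avoiding data loss) and circular shifting
rotates the whole series; both preserve autocorrelation at lags below the
block length. Neither scheme is canonical — which blockwise null is best
for neuroimaging data is an open question — so both are exposed.

The built-in univariate estimators use a vectorized path (rank transform
per cell computed once, per-class variances or correlations evaluated
across the whole grid per permutation); it is asserted equal to the generic
per-cell path to 1e-10. Runs are bit-reproducible given the seed.

## Synthetic data

The generators emulate the study conditions the estimators are validated
on: bivariate/trivariate Gaussians with stated correlations; two stimulus
features with covariance 0.6 driving responses (noise s.d. defaults to 1.0,
a free parameter of the design); two-class spectral coefficients with von
Mises phase and chi-square amplitude (defaults: concentration 2.0, shared
dof 3, class dofs 2 and 8 — chosen to give a clear but non-saturated effect,
and exposed as parameters); event-related Gaussian noise grids with planted
class-mean or continuous-feature modulations, including sign-flipping
profiles; low-pass-filtered (3rd-order Butterworth, zero-phase) lagged
pairs for the continuous design; and outlier corruption replacing a
fraction of trials with noise at 5× the signal s.d.

What these generators do **not** emulate: realistic M/EEG forward models,
spatial channel correlations, non-stationarity, or non-Gaussian copula
structure in the null. Passing tests therefore demonstrate estimator and
inference correctness under the stated models, not performance guarantees
on real recordings (where the lower-bound slack can be material).

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 100 null datasets × 200 permutations on a
20 × 50 grid for the FWER check; 100 replicates per condition for the
bias/MSE comparisons (N up to 4096); 600 replicates per (k, N) cell for the
unbiasedness property. Covariances use divisor N−1 about the sample mean;
positive-definiteness is enforced by Cholesky with a pivot-ratio guard
(relative pivot² < 1e-12 raises, flagging collinear columns). The G-test
χ² goodness-of-fit check uses 3×4 tables at N = 1000: at small tables the G
statistic is too discrete for a meaningful Kolmogorov–Smirnov comparison
against the continuous χ² regardless of estimator correctness.

## Known limitations

- Only Gaussian-copula dependence is measured; tail dependence and
  rank-symmetric structure are invisible (by design, as a lower bound).
- The discrete variable in mixed MI is univariate.
- Ties are handled by deterministic ordinal ranking with a warning; heavy
  ties violate the continuous-data assumption and bias the estimate.
- DI/DFI use uniform consecutive-lag embeddings; non-uniform embeddings and
  model-order selection are out of scope.
- Simulated effect sizes depend on generator parameters (noise s.d.,
  concentration, dof) that are conventions of this package; tests assert
  quantitatively only population-forced values (zeros, closed forms,
  numerically integrated oracles), and treat the rest qualitatively.
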