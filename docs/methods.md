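# Methods

## The testing problem

Microbiome differential abundance analysis asks, taxon by taxon, whether a
taxon's (normalized) abundance Y is associated with a clinical variable C
(binary or quantitative) after adjusting for covariates Z.  Microbiome
counts are zero-inflated, over-dispersed, heavy-tailed and often multimodal,
so parametric models for the (transformed) counts tend to inflate the type I
error, while plain non-parametric tests lose power and cannot adjust for
covariates.  This package takes a two-part, quantile-based route that makes
no distributional assumption on the positive part and therefore works under
any normalization.

## The two-part quantile model

The outcome is modeled in two pieces:

* presence: `logit P(Y > 0 | X) = Z'ζ + γ C`
* positive part: `Q_Y(τ | X, Y > 0) = Z'α(τ) + β(τ) C` for τ ∈ (0, 1)

The global null is `γ = 0 and β(τ) = 0 for all τ`: the variable affects
neither the chance of observing the taxon nor any quantile of its abundance
when observed.  When Y is a count, a perturbation `W = Y + U`, `U ~ U(0,1)`
iid, is added before quantile fitting to break ties (the zero/non-zero mask
is always taken from the raw Y, never from W).

## The test

**Step 1 — presence.**  Any valid test of `γ = 0` in the logistic model.
The default is the likelihood-ratio test; under separation or
non-convergence the implementation falls back to Rao's score test, which
needs only the null fit and is always defined.  All-zero and zero-free taxa
are degenerate for this step and are flagged.

**Step 2 — quantiles.**  For each τ on a grid, a zero-adjusted rank-score
test of `β(τ) = 0`.  Let `C~ = C·I(Y>0)`, `Z~ = Z·I(Y>0)` and
`C* = (I − Z~(Z~'Z~)⁻¹Z~')C~` (the least-squares residual of C~ on Z~).
With `α̂(τ)` the pinball-loss minimizer on the non-zero subset under
`β = 0`, the score and statistic are

    S_τ = n^{-1/2} Σ_i ψ_τ(W_i − Z_i'α̂(τ)) I(Y_i>0) C*_i,
    T_τ = S_τ / sqrt(n⁻¹ τ(1−τ) C*'C*),        ψ_τ(u) = τ − I(u<0).

T_τ is asymptotically standard normal under the null.  The point of the
zero-truncated C* is that its second moment carries P(Y>0|X): a naive
rank-score test restricted to the positive subset would treat that subset as
fixed and underestimate the variance, biasing the test under zero inflation.
Across the grid the scores are jointly normal with the Brownian-bridge
covariance `Σ_kl = n⁻¹(min(τ_k,τ_l) − τ_k τ_l) C*'C*`, positive
semidefinite by construction.

**Step 3 — combination.**  Two combiners of `p_L, p_{τ_1}, …, p_{τ_K}`:

* Cauchy: `T = r̂ tan((0.5−p_L)π) + Σ_k w_k tan((0.5−p_k)π)` with the
  observed zero proportion r̂ as the presence weight and
  `w_k ∝ (1−r̂)[τ_k I(τ_k≤0.5) + (1−τ_k) I(τ_k>0.5)]`, all weights summing
  to one.  T is standard Cauchy under the null regardless of the dependence
  between components, so `p = 0.5 − arctan(T)/π`.
* MinP: the smallest marginal p-value `T_min` calibrated against the joint
  null law, `p = 1 − (1−T_min)·P(all quantile p's > T_min)`, using the
  asymptotic independence of the logistic and rank-score statistics; the
  joint probability is estimated by drawing B score vectors from
  `N(0, Σ̂)` (default B = 10,000, with the binomial Monte-Carlo SE of the
  estimate reported alongside).

## Conventions and numerical choices

These choices are pinned because the statistic can depend on them:

* `ψ_τ(0) = τ` (the lower piece of the pinball-loss derivative is taken at
  exactly-zero residuals).  With continuous perturbed outcomes exact zeros
  occur only at the interpolated fit points, but the quantile fit always
  interpolates observations, so the convention matters.
* Quantile-fit tie-break: when the pinball minimizer is an interval (even
  split of an intercept-only fit on discrete data) the lower vertex is
  taken.  Intercept-only designs use the order statistic at position
  `ceil(mτ)` in closed form; general designs solve the exact
  quantile-regression linear program (HiGHS).  We author the LP fit rather
  than reuse an iterative smoothing solver precisely to control this vertex
  convention.
* Marginal p-values are two-sided (`2(1−Φ(|T|))`), reading the alternative
  as association in either direction; the MinP calibration operates on the
  p-value scale with the same two-sided convention.
* One perturbation draw per run, governed by the run seed; the `zinq_table`
  driver derives one sub-seed per taxon from a single base seed, so results
  are bit-reproducible and independent of chunking.
* Cauchy numerical guards: p-values are clipped to [1e-15, 1−1e-15], the
  tangent is evaluated as `cot(πp)` (accurate for tiny p), and for
  `T > 1e7` the output uses the asymptote `1/(πT)`.
* NA components (degenerate sub-tests) are dropped from the Cauchy
  combination and the remaining weights renormalized to one, which keeps
  the standard-Cauchy null law; in MinP a missing logistic p drops the
  `(1−T_min)` factor.

## Grid policy and degenerate taxa

Default grids: τ = 0.1, 0.25, 0.5, 0.75, 0.9 for continuous data with at
least 30 non-zero observations; τ = 0.25, 0.5, 0.75 for discrete data (raw
or rarefied counts, where the perturbation injects extra noise) or fewer
than 30 non-zeros.  A user grid is honored when it has fewer levels than
non-zero observations.  Below 15 non-zeros the quantile part is refused
(quantile regression is unstable far from the median on so few points) and
the taxon is flagged `low_prevalence`; its combined p-value is then the
logistic p-value alone.  All-zero taxa produce no test; zero-free taxa skip
the logistic part (its Cauchy weight r̂ = 0 vanishes anyway).  The quantile
part additionally requires m ≥ p + 2 non-zeros.

## Normalization

Rarefaction is a per-sample multivariate-hypergeometric subsample (without
replacement) to a common depth; `rarefy_average` averages several
independent rarefactions to build smooth starting data for simulation.  TSS
divides by library size.  CSS divides by the cumulative count up to a fixed
quantile of the sample's positive counts; the quantile defaults to 0.5 with
scale 1000, with the empirical quantile taken as the lowest positive value
at or above the nominal level (order statistic, no interpolation) — a fixed
rather than adaptive quantile, the simplest reading of the definition.  CLR
centers log counts per sample; zeros are handled by a pseudocount (default
0.5), by refusal, or by the "keep zeros" variant that restores original
zeros after the transform so presence/absence testing still operates.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure of real 16S genus tables
— zero inflation with covariate-dependent presence, arbitrary positive-part
shapes, over-dispersed compositional counts — without any cohort data:

* edf mixtures resample two groups' observed abundances, with the effect
  diluted by mixing pools (mix 1.0/0.8/0.6 gives decreasing effects; 0.5 is
  the null).  The stand-in edf pair (`synthetic_edf_pair`) is zero-inflated
  log-normal with a log-scale location shift of 0.5 between groups and 30%
  zeros in each pool, sizes 600 — a synthetic construction, not fitted to
  any cohort.
* the two-part generator draws presence from the logistic part and, when
  present, inverts the fitted conditional quantile function (fine grid
  τ = 0.01…0.99, linearly interpolated) at U ~ U(0,1), rounding to the
  nearest integer.  Raw per-τ fits can cross, so the 99 evaluated quantiles
  are monotone-rearranged (sorted) per covariate profile before inversion —
  inverse-CDF sampling is ill-defined otherwise.  Rounded values below 1
  while present are clamped to 1 (and counted): without the clamp the
  realized zero proportion would contradict the fitted presence model.
* the Dirichlet-multinomial generator draws a composition per sample and
  counts multinomially at its library size; fitting is by method of moments
  (closed form and stable — accuracy beyond matching mean proportions and
  over-dispersion is not needed for a generator).
* joint covariate permutation preserves covariate inter-correlations while
  severing their link to the counts.

The benchmark catalogue (`synthetic_benchmark_params`) spans prevalence
10–95%, log-normal-like and heavy-tailed (Pareto) positive parts, and
location-shift, spindle (upper-quantile), crossing (sign-changing),
presence-only and null effects.

What the generators do not emulate: between-taxon correlation (taxa are
generated independently except for the compositional coupling in the DM
design), longitudinal structure, and library-size confounding with the
variable of interest.  Passing calibration on these nulls therefore shows
correctness of the statistics, not robustness to those real-data features.

## Calibration conditions and problem sizes

The package's own acceptance study uses a fully specified null: n = 300
samples, C ~ Bernoulli(0.5), presence ~ Bernoulli(0.7) independent of C,
positive part log-normal(0, 1) independent of C, default five-point grid,
5000 replicates, MinP with 10,000 draws.  5000 replicates put the 3-SE
calibration band at ±0.009 around 0.05; the Cauchy combiner is known to be
very slightly anti-conservative in finite samples, which is visible but
within that band.  Other study sizes: covariance oracle, 5000 score draws
at n = 300; MinP/Cauchy concordance, 500 taxa spanning effects 0–1;
parameter recovery, one table at n = 5000; power ordering, 1000 replicates
per mixture at n = 600; heterogeneity diagnostic, 500 replicates per effect
shape at n = 300.

## Heterogeneity diagnostic

For a taxon of interest the full two-part model (variable included) is
fitted and the coefficient of variation |sd/mean| (sample sd, n−1) of the
20 variable coefficients — logistic γ̂₁ and β̂₁(τ) at τ = 0.05, …, 0.95 —
summarizes how heterogeneous the association is.  A homogeneous location
shift gives near-constant coefficients and a small CV; crossing or
tail-concentrated effects give a large (possibly infinite, when the mean
is ~0) CV.

## Known limitations

* The rank-score asymptotics need a reasonable number of non-zero
  observations; below ~15 the quantile part is refused by design.
* When library size is confounded with the variable of interest, no
  zero-inflation-aware test can separate undersampling from true absence;
  incorporating library size as a covariate is possible but methods that
  treat relative abundance quantitatively may be preferable.
* Confidence intervals / estimation for β(τ) ≠ 0 and omnibus combination
  across normalizations are out of scope.
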