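# Methods and numerical conventions

This note records the mathematical conventions, algorithmic choices and known
limitations of the package. It is the companion to the API docstrings: the
docstrings say *what* each function computes, this note says *why* it is
computed that way.

## 1. The distribution

Density, with α > 0, β > 0 and D = β² + αβ² + 2:

```
f(x) = (β³/D)(α + βx + x²) e^{−βx}
S(x) = e^{−βx} [1 + (β²x² + (β³ + 2β)x)/D]
h(x) = β³(α + βx + x²) / (β²x² + (β³ + 2β)x + D)
```

The survival function is evaluated from its explicit expression rather than
as 1 − F to stay accurate deep in the tail. The hazard tends to β as x → ∞.

**Gamma-mixture representation.** Expanding the quadratic factor,

```
f(x) = w₁·Gamma(1, β) + w₂·Gamma(2, β) + w₃·Gamma(3, β),
(w₁, w₂, w₃) = (αβ², β², 2)/D,
```

with Gamma(k, β) the gamma density with shape k and rate β. The sampler draws
a component index from (w₁, w₂, w₃) and then a gamma variate — exact, fast
and free of accept/reject loops.

**Shape classifiers.** The density is unimodal when
`disc = β⁴ − 4αβ² + 4 > 0` and `√disc − β² + 2 > 0`, with mode
`(√disc − β² + 2)/(2β)`; otherwise it is reported decreasing with the mode
location 0. Note that the unimodal branch reports the interior stationary
local maximum; for extreme parameter corners (large α with small β) the
global maximum of the density can still sit at 0.

The hazard derivative has the sign of the quadratic
`2βx² + 2(β² + 2)x + β(β² + 2 − 2α)`. Its leading and linear coefficients are
positive, so only two shapes can occur: **increasing** when 2α ≤ β² + 2 and
**bathtub** when 2α > β² + 2 (equivalently β² + 2 − √(−β⁴ + 4αβ² + 4) < 0). A
strictly decreasing hazard is impossible in this family; the enum member
exists for API completeness only.

**Quantiles.** No closed-form inverse CDF exists (the usual Lambert-W trick
does not apply to a quadratic polynomial factor). `quantile` brackets the
root geometrically starting from mean + 50/β and applies Brent's method with
xtol = 1e−14. The simulation engine uses a vectorized bisection
(`_quantile_batch`, 80 iterations) when many probabilities are inverted at
once.

## 2. Derived measures

* Raw moments: `E[Xʳ] = [Γ(r+3) + β²Γ(r+2) + αβ²Γ(r+1)] / (βʳ D)`.
* Incomplete moments via unnormalized lower incomplete gamma functions
  (scipy's regularized `gammainc` times Γ).
* MGF: `C[α/(β−s) + β/(β−s)² + 2/(β−s)³]` for s < β (the gamma-mixture MGF).
* Skewness/kurtosis are reported twice: `_paper` variants are the raw-moment
  ratios `E[X³]/Var^{3/2}` and `E[X⁴]/Var²` used in some applied tables;
  `_std` variants are the usual standardized central moments. Callers choose
  explicitly.
* Limited expected value:
  `E(X∧u) = [K − (β²u² + (4β + β³)u + K) e^{−βu}]/(βD)` with
  `K = 6 + 2β² + αβ²`; equal to T₁(u) + u·S(u) and quadrature-verified.
* TVaR and tail variance use closed forms verified against quadrature; the
  level-p report bundles VaR, TVaR, TV, mean excess and limited EV.
* **Mean excess ships two deliberately different forms.** `form="integral"`
  evaluates the defining `∫ₓ^∞ S(u)du / S(x)` (tends to 1/β for large x).
  `form="paper"` evaluates a product formula that circulates in applied work
  and reproduces its published numeric table but is *not* the same function —
  it grows polynomially in x. The `form` argument is mandatory so no caller
  silently gets the wrong convention.
* Rényi entropy: closed double-binomial series for integer order ≥ 2,
  adaptive quadrature for any other positive order ≠ 1; the two agree to
  ~1e−12 where both apply.
* Fuzzy reliability uses a triangular membership function with knots
  t₁ < t₂ at λ-cut level λ: `R = S(t₁) − S(x(λ))` with
  `x(λ) = t₁ + λ(t₂ − t₁)`. It is monotone in λ and t₂ by construction;
  it is antitone in t₁ where the density is decreasing (in particular beyond
  the mode), but not globally — on a rising stretch of the density the
  direction can reverse.

## 3. Estimation

Fifteen methods share one dispatcher; every criterion is **minimized** (the
maximum-product-of-spacings value is stored negated). With x₍ᵢ₎ the ascending
order statistics, F/S the fitted cdf/survival at x₍ᵢ₎, and
Λᵢ = F(x₍ᵢ₎) − F(x₍ᵢ₋₁₎) the n+1 CDF spacings:

| tag | criterion |
|---|---|
| mle | −2·logL |
| ade | −n − (1/n)Σ(2i−1)[ln Fᵢ + ln S₍ₙ₊₁₋ᵢ₎] |
| cvme | 1/(12n) + Σ[Fᵢ − (2i−1)/(2n)]² |
| mpse | −(1/(n+1))Σ ln Λᵢ |
| olse | Σ[Fᵢ − i/(n+1)]² |
| rtade | n/2 − 2ΣFᵢ − (1/n)Σ(2i−1) ln S₍ₙ₊₁₋ᵢ₎ |
| wlse | Σ wᵢ[Fᵢ − i/(n+1)]², wᵢ = (n+1)²(n+2)/(i(n−i+1)) |
| ltade | −3n/2 + 2ΣFᵢ − (1/n)Σ(2i−1) ln Fᵢ |
| msade | Σ|Λᵢ − 1/(n+1)| |
| msalde | Σ|ln Λᵢ − ln(1/(n+1))| |
| adsoe | 2Σ ln Fᵢ + (1/n)Σ(2i−1)/Fᵢ |
| ke | max₁≤ᵢ≤ₙ max(i/n − Fᵢ, Fᵢ − (i−1)/n) |
| mssd | Σ(Λᵢ² − 1/(n+1)) |
| mssld | Σ(ln Λᵢ − ln(1/(n+1)))² |
| mslnd | Σ[e^{Λᵢ − 1/(n+1)} − (Λᵢ − 1/(n+1)) − 1] |

Conventions worth noting:

* **Anderson–Darling index pairing.** In `ade` and `rtade` the weight (2i−1)
  pairs with the *reversed* survival term S(x₍ₙ₊₁₋ᵢ₎). For `rtade` this was
  verified numerically: the reversed form equals the defining right-tail
  integral `n∫(Fₙ − F)²/(1 − F) dF` to 1e−13, while the unreversed variant is
  not a distance at all (its minimizer drifts to α → ∞). `ltade` needs no
  reversal (verified against `n∫(Fₙ − F)²/F dF`).
* **ADSOE.** The default is the divided form with (2i−1)/Fᵢ; a literal
  undivided variant (2i−1)·Fᵢ is available behind `adsoe_as_printed=True` for
  fidelity experiments but is unbounded below and not recommended. Note the
  divided-form minimizer is itself noticeably biased for α at practical
  sample sizes — ADSOE ranks worst in the simulation studies.
* **Guards.** F and S are clipped to [1e−300, 1 − 1e−16] inside logarithms;
  spacings are clipped below at 1e−300; exact ties are broken by a
  deterministic jitter (k·1e−9·scale on the k-th repeat) before spacings are
  formed. Degenerate evaluations return large finite values instead of
  raising, so optimizers can recover.

### Optimizers — and why there are two

* **Library default (data analysis):** deterministic multi-start Nelder–Mead
  on (log α, log β) — the supplied/auto start, four local perturbations, and
  three diverse moment-scale starts; tolerances 1e−10, 5000 evaluations per
  start. This converges tightly and is what `NTPQEDModel.fit` uses.
* **Simulation engine with `init_at_truth=True` (benchmarking protocol):**
  a single finite-difference BFGS search in natural parameter space started
  at the true parameters. On smooth criteria this fully converges. On the
  nonsmooth max/absolute-value criteria (notably the Kolmogorov distance)
  the line search loses precision almost immediately and the search
  terminates near its starting point. This is deliberate: estimator
  benchmarking studies in this literature are conventionally run by handing
  every criterion to a quasi-Newton routine initialized at the truth, and
  the characteristic, much-smaller Kolmogorov-estimator biases those studies
  report are reproducible only under that protocol. A fully converged
  minimum-Kolmogorov fit has α-MAE an order of magnitude larger. The switch
  is exposed so users can run either protocol; the default (False) uses the
  library path with data-driven starts.

**Standard errors** (MLE only): Wald SEs from the inverse observed
information, with the Hessian by central finite differences
(statsmodels' `approx_hess`). A non-positive-definite information matrix
(flat likelihood, boundary-adjacent α) yields NaNs plus a warning.

## 4. Monte-Carlo engine

Per scenario (true Params, n, M replicates, seed): replicate samples are
drawn from per-replicate substreams spawned off one `SeedSequence`, so every
method sees identical data and runs are bit-reproducible. Six metrics per
method and parameter: mean absolute bias, MSE, mean relative error, mean and
max absolute CDF discrepancy between true and fitted laws at the sample
points, and the average scaled absolute error between observed order
statistics and fitted quantiles at i/(n+1). Methods are ranked per metric
with average-rank ties; rank sums are ranked overall, and
`aggregate_ranks` accumulates rank sums across scenarios into a grand table.
Non-converged fits are kept (best-so-far values) and counted in `n_failed` —
dropping them would understate bias.

## 5. Model comparison

Competitors (all positive-valued, one or two parameters): exponential
(closed-form MLE), Burr X `F(x) = (1 − e^{−(θx)²})^λ`, Nadarajah–Haghighi
`F(x) = 1 − exp(1 − (1 + θx)^α)`, XLindley `f(x) = (θ/2)(1 + θx)e^{−θx}`,
and its inverse-variable counterpart
`f(x) = (δ/2)(1 + δ/x)e^{−δ/x}/x²` (heavy-tailed; its cdf
`e^{−δ/x}(2 + δ/x)/2` approaches 1 slowly). One-parameter families are
fitted by bounded scalar minimization of the negative log-likelihood in log
space; two-parameter families by multi-start Nelder–Mead.

Goodness of fit is computed from the probability-integral transforms
uᵢ = F(x₍ᵢ₎; fitted): KS (max one-sided deviation), CVM (plotting-position
form), AD (standard log form). Information criteria: AIC = −2logL + 2k,
HQIC = −2logL + 2k·ln(ln n).

**p-value convention:** asymptotic simple-hypothesis null distributions
evaluated at the estimated parameters — no Lilliefors-type correction, no
bootstrap. KS uses the Kolmogorov limit law via two dual series (switch at
t = 1.18, continuity-tested); CVM delegates to scipy's one-sample test
against the uniform law; AD uses the Marsaglia & Marsaglia (2004)
approximation to the limit CDF. Because parameters are estimated, these
p-values are approximations by construction; for small tie-free samples an
exact-distribution KS p-value (as R's `ks.test` computes) differs in the
2nd–3rd decimal.

## 6. Known limitations

* α is weakly identified when the fitted density is near its α → 0 boundary
  (the likelihood flattens); such fits are flagged as near-degenerate and
  their Wald SEs are NaN.
* The `form="paper"` mean-excess product formula diverges from the integral
  definition away from small thresholds; it exists for table fidelity only.
* Asymptotic p-values with estimated parameters are conservative
  approximations.
* The truth-initialized benchmarking protocol is a study convention, not an
  estimator one could deploy on real data (the truth is unknown there); use
  the default optimizer path for data analysis.
* Censoring, truncation, Bayesian inference and interval estimation beyond
  Wald SEs are out of scope.
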