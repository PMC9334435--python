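# Methods

## Model overview

`ramlmodel` implements a mechanistic two-mutation model of
radiation-induced acute myeloid leukemia (rAML) in male CBA/H mice. The
major murine rAML pathway is driven by two hits to the *Sfpi1* gene
(encoding PU.1): a radiation-induced interstitial chromosome-2 deletion
with *Sfpi1* copy loss creates pre-leukemic intermediate cells, and a
point mutation in the remaining allele converts an intermediate cell into
a malignant one. The model tracks the expected numbers of normal (*N*),
intermediate (*I*) and malignant (*M*) bone-marrow cells and turns them
into a lifetime rAML probability by competing the potential diagnosis
time against death from other causes.

### Cell killing and deletion induction

Radiation kills clonogenic cells according to the linear-quadratic (LQ)
model, `L(D) = α·D + β·D²` expected lethal events and survival
`S(D) = exp(−L(D))`. Low-dose hyper-radiosensitivity (HRS) is described
with the induced-repair model, in which the linear coefficient is
dose-dependent:

    α(D) = α_r (1 + (α_s/α_r − 1) e^(−D/D_c)),

interpolating from a steep low-dose slope `α_s` to the conventional
`α_r` with characteristic dose `D_c` (the dose at which induction of
increased radioresistance is 63% complete). Deletion induction is
proportional to lethal events with probability `μ_del` per lethal event.

Three target-cell scenarios are supported:

| scenario | killing | deletion induction |
|----------|---------|--------------------|
| `HRS-`   | LQ      | LQ |
| `HRS+1`  | induced repair (`α_s = 20/Gy`) | LQ |
| `HRS+2`  | induced repair (`α_s = 20/Gy`) | induced repair with slope ratio `α_s/α_r = 3` |

The deletion slope ratio of 3 for `HRS+2` reflects chromosomal-aberration
dose responses with ratios between 2.5 and 3.5; it enters only the
deletion terms (the `L̂_HRS` function), never cell killing. Note that the
published in-text ODE shorthand for `HRS+2` reuses the cell-killing HRS
rate in the deletion term; this package follows the closed-form initial
condition, where deletion is driven by `L̂_HRS`, and keeps the ODE
integrator consistent with that choice.

### Acute exposure and closed forms

Acute exposure (constant dose rate, duration `T = D/Ḋ ≈ 0`) admits a
closed-form count of intermediate cells surviving exposure,

    I₀(D) = N₀ exp(−(L_kill + μ_del L_del)) · expm1(μ_del L_del),

with the scenario-specific killing/deletion terms above. During exposure
intermediate cells neither proliferate nor transform (the derivation
assumption); afterwards `I(t) = I₀ e^((b−μ_p)t)` and
`M(t) = μ_p/(b−μ_p)·(I(t) − I₀)`. The during-exposure ODE system is also
integrated numerically (`integrate_exposure_ode`) with the same
during-exposure terms, which makes the closed form an exact acute limit;
the integrator exists purely as a cross-check and reproduces `I₀` to
better than 0.1% at 10⁴ Gy/month.

Malignant-cell arrival is an inhomogeneous Poisson process with rate
`Ṁ(t) = μ_p I(t)`, so the first-arrival density is
`f_{M=1}(t) = Ṁ(t) e^(−M(t))`. Diagnosis trails the first malignant cell
by a fixed latency `t_lag = 5.06` months (a 22-week median AML latency in
PU.1-null mice, converted at 365.25/12 days per month), giving the
potential diagnosis density `f_A(t) = f_{M=1}(t − t_lag)`.

### Competing mortality and incidence

Non-rAML death times follow an Azzalini skew normal with location
`ξ(D) = 25.86 − 0.57·D` months, scale `ω = 5.87` months and shape
`−1.01`, chosen to reproduce mean survival falling from 22.5 months
(0 Gy) to 19.1 months (6 Gy) with sd 4.83 months and skewness −0.141.
Negative times are removed by renormalizing the CDF on `t ≥ 0`
(`F̂(t) = (F(t) − F(0))/(1 − F(0))`); the truncated mass is < 10⁻⁵ at the
defaults, and moments are reported for the uncorrected distribution.
Note the corrected CDF lies *below* the raw CDF
(`F̂ − F = F(0)(F−1)/(1−F(0)) ≤ 0`), i.e. the correction raises the
survival probability at every time.

The actual diagnosis-time density is the improper density
`f_d(t) = (1 − F̂(t)) f_A(t)` and the lifetime probability is
`P(rAML) = ∫ f_d dt < 1`. Cumulative incidence in time is the running
integral of `f_d`.

## Numerical choices

- **Quadrature.** `raml_probability` uses adaptive quadrature
  (`scipy.integrate.quad`, absolute tolerance 1e-10) in the shifted
  variable `s = t − t_lag`, so the kink of `f_A` at `t_lag` sits at the
  integration boundary. The integration horizon is the first time at
  which the corrected survival drops below 1e-10, capped at 120 months —
  beyond it the survival multiplier annihilates the density.
- **Batch route.** Dose-response curves and the fitting loop use a
  fixed-order (256-node) Gauss–Legendre rule vectorized over doses; the
  integrand is smooth on the truncated horizon and the two routes agree
  to < 1e-8 (asserted in the tests).
- **Low-dose precision.** `I₀` uses `expm1`, since `μ_del·L ≈ 1e-4` at
  0.05 Gy and the low-dose behaviour is the whole point of the HRS
  analysis.
- **Degenerate growth.** `b ≤ μ_p` is rejected rather than handled by a
  limit form; the parameterization of interest always has `b ≫ μ_p`.
- **Cumulative incidence** uses a 4001-point trapezoidal grid from
  `t_lag` to the horizon (plateau agrees with the adaptive quadrature to
  < 1e-6).
- **HRS rate during exposure.** The induced-repair α in the lethal-event
  *rate* is evaluated at the protocol's total dose and held constant
  during the exposure (the literal reading of the printed rate), not
  re-evaluated at the running dose.
- **`D_c` units.** `D_c` is a dose in Gy (the exponent `−D/D_c` requires
  it), regardless of the inconsistent unit annotations that sometimes
  accompany induced-repair parameter tables.

## Parameters

| symbol | default | unit | meaning |
|--------|---------|------|---------|
| `α_r` | 0.0402 | /Gy | conventional LQ linear coefficient |
| `α_s` | 20 | /Gy | low-dose HRS slope (cell killing) |
| `D_c` | 0.06 | Gy | radioresistance-induction dose |
| `β` | 0.122 | /Gy² | LQ quadratic coefficient |
| `μ_del` | 0.0498 | – | deletion probability per lethal event |
| `N₀` | 15670 | cells | initial HSC count |
| `b` | 0.0995 | /month | intermediate proliferation rate (fitted) |
| `μ_p` | 2.17e-5 | /month | point-mutation rate (fitted) |
| `t_lag` | 5.06 | months | diagnosis latency |
| `ξ` | 25.86 − 0.57·D | months | mortality location |
| `ω` | 5.87 | months | mortality scale |
| shape | −1.01 | – | mortality skewness parameter |

The shipped `b` and `μ_p` defaults are the published fitted values. They
were estimated against the historical Major/Mole cohort data, which are
not distributed with this package; they are therefore documented
defaults, reproducible only against those external datasets.

## Fitting

`fit_proliferation_parameters` minimizes

    C(p) = Σᵢ (w₁(i)(y(i) − ŷ(i,p)))² + Σᵢ (w₂ (z(tᵢ)/z(t₂₀) − ẑ(tᵢ,p)/ẑ(t₂₀,p)))²

over `p = (b, μ_p)`, where `y` are 20 dose-group incidence percentages
weighted by the fraction of mice per point (`w₁(i) = nᵢ/Σn`), and `z` is
the 20-point cumulative incidence after acute 4.5 Gy normalized to its
final point and weighted by the mean observed 4.5 Gy incidence percent
(`w₂`; mouse-weighted mean when several 4.5 Gy records exist). The two
sums are stacked as a 40-element residual vector so that a
Levenberg–Marquardt least-squares pass minimizes `C(p)` exactly;
positivity is enforced by optimizing `log b`, `log μ_p`. Standard errors
are the usual independent-residual asymptotics `s²(JᵀJ)⁻¹` with
`s² = C/(n−k)`, delta-method mapped back to the natural scale. Cohorts
with a single distinct dose are flagged non-identifiable; non-convergence
is flagged, not raised.

## Stochastic oracle

`simulate_cohort` draws, per mouse, an exact Poisson first-arrival time
(inverting the closed-form `M(t)` against an Exp(1) variate — no time
discretization) and an independent truncated-skew-normal death time
(rejection of negative draws; acceptance ≈ 1), then applies the rule
`t_A = t_{M=1} + t_lag ≤ t_Ā`. Seeds are split into independent
substreams for the two event types, and mouse *i* consumes element *i* of
each stream, so results do not depend on iteration order. The oracle is
fully independent of the quadrature pipeline and agrees with it within 3
binomial standard errors at n = 10⁵ across doses and scenarios.

## Synthetic data

The historical incidence tables are not public, so
`generate_cohort_dataset` emulates their structure: 5 dose groups (0.75,
1.5, 3.0, 4.5, 6.0 Gy) × 4 replicate experiments with 50 mice each (200
per dose group — the historical programmes followed on the order of a
thousand mice over the dose groups), and a 400-mouse 4.5 Gy time course
observed at 20 equally spaced times on [6, 30] months. Replicate case
counts are Binomial(n, P(dose)); time-course case times are inverse-CDF
draws from the normalized analytic diagnosis-time density, accumulated
at the observation times. The noise-free mode reports analytic values
directly (the infinite-mice limit), making parameter recovery a sharp
self-consistency check (recovery to ≪ 0.1%).

What the generator does *not* emulate: between-experiment heterogeneity
(housing effects, which historically produced incidence variation well
beyond binomial), minor non-*Sfpi1* rAML pathways, censoring and
cause-of-death misclassification. Passing recovery tests therefore
demonstrate internal consistency of the estimator under the model's own
sampling assumptions, not robustness to those real-data features.

## Known limitations

- **Interval coverage.** In a 200-cohort simulation study the median
  estimates are essentially unbiased (within ~0.5% for `b`, ~2% for
  `μ_p`), but ±2SE intervals cover the truth in only ~25% (`b`) / ~55%
  (`μ_p`) of cohorts. The cause is structural: the 20 normalized
  cumulative-incidence residuals are correlated empirical-CDF deviations,
  which the independent-residual asymptotics `s²(JᵀJ)⁻¹` cannot see, so
  the SEs understate the sampling spread by a factor of roughly five —
  independently of cohort size. Any published ±SE derived from this cost
  with the same recipe carries the same caveat. Treat the reported SEs as
  curvature diagnostics, not calibrated uncertainties; a bootstrap over
  synthetic cohorts gives realistic spreads.
- **Sampling spread of the estimates.** Under binomial/multinomial noise
  at the historical cohort scale the median |relative error| of `b̂` and
  `μ̂_p` is ~20%; it shrinks only as 1/√n of the time-course case count.
- **HRS+2 crossing.** The HRS+2 incidence excess over the control holds
  only below ≈ 0.066 Gy with the default parameters; above that the
  `α_s = 20` extra killing outweighs the ratio-3 deletion boost. The
  three scenario curves agree within 1% above 0.5 Gy.
- **Induced-repair fit quality.** The induced-repair parameters cannot
  describe the steepest observed HRS survival data exactly (0.64 modeled
  vs ~0.65 observed at 0.06 Gy with the defaults; 0.79 vs 0.65 with the
  in-vitro LT-HSC estimates); no steeper alternative HRS model is
  implemented.
- **Extrapolation.** Mortality parameters were derived for 0–6 Gy;
  dose-response output beyond 6 Gy is flagged in run metadata. The model
  is acute-exposure only (no fractionation schedules) and applies to the
  major *Sfpi1*-driven pathway in male CBA/H mice — not to human AML.
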