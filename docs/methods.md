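# Methods

## The model

The unit of analysis is the household. Each household *h* lives in a
census block group *g(h)* that carries an Area Deprivation Index score
`adi ∈ {1..100}` (higher = more deprived), a median annual household
income `m_g` with an ACS margin of error `moe_g`, a median monthly rent
and an annual food-expenditure estimate.

**Income imputation.** ACS margins of error are 90% confidence
half-widths, so the implied standard error is `σ_g = moe_g / 1.645`
(`moe_convention="acs90"`, default; `"sd"` treats the MOE as a standard
deviation directly, for sensitivity checks). Household income is drawn
uniformly on `[m_g − σ_g, m_g + σ_g]` — the minimal reading of "a random
value within one standard deviation"; a truncated-normal variant on the
same interval is available behind `IncomeDrawConfig.distribution`. The
draw is rescaled by the WHO equivalence scale

    income(h) = draw · (size_h / 2) ** 0.56

with reference size 2 (the cohort median) and exponent β = 0.56 from the
catastrophic-health-expenditure literature; both are configurable and the
adjustment can be switched off. The scale *multiplies* income for larger
households (a size-4 household with base draw 30,000 gets
30,000 · 2^0.56 ≈ 44,228.08). Results are floored at 0.

**Subsistence and capacity to pay.** Subsistence is
`12 · rent_monthly + food_annual`; non-subsistence expenditure is
`NSE = income − subsistence` and may be negative. The poverty flag
compares the (size-adjusted) imputed income with the HHS federal poverty
guideline, a configurable `base + increment · (size − 1)` table shipped
with the 2018 values for the 48 contiguous states ($12,140 + $4,320 per
additional person) to match the study year of the emulated data.

**The catastrophe rule.** A scenario is `(burden b, cost C, threshold τ)`
with defaults C = $17,875 (average 2018 Florida cholecystectomy) and
τ = 0.40. A household is flagged when `b·C > τ·NSE`, with *strict*
inequality: a payment exactly equal to 40% of capacity is not
catastrophic. Any `NSE ≤ 0` is flagged under every scenario, because the
left side is positive. The WHO capacity-to-pay variant that substitutes a
poverty-line subsistence for food-poor households is deliberately not
implemented; the rule operates on NSE directly. All scenarios are
evaluated on one shared set of income draws, so scenario differences are
attributable to the burden assumption alone; the nestedness of flags
across burdens is an invariant the tests check.

**Uninsurance adjustment.** Population risk percentages can be rescaled
by the uninsured fraction *p* (default 0.804): the simple product
`p · pct` (1 decimal) is a lower bound treating insured households as
risk-free at the uninsured burden; a two-component mixture
`p · pct(uninsured) + (1−p) · pct(insured)` is provided as the variant
that instead assigns insured households the insured-burden risk.

## Association statistics

**Phi-K.** ADI is binned into 10 fixed-width bins over 1..100 (matching
the decile presentation; count configurable), the outcome stays binary.
From the 2×10 contingency table the Pearson chi-square is computed; the
sampling pedestal `(r−1)(c−1)` — the chi-square expected under
independence from noise alone — is subtracted (the correction can be
disabled). The corrected value is then matched to the chi-square of a
standard bivariate normal binned on the grid whose interval masses equal
the empirical margins; `χ²(ρ)` is strictly increasing on [0, 1), so the
solving ρ is found by Brent root-finding (xtol 1e-10) on
[0, 1 − 1e-7]. Values at or below the pedestal return 0; tables whose raw
chi-square reaches the binned distribution's maximum saturate at 1.
Because the binned normal is not symmetric under swapping an asymmetric
binary margin, rows are first put in canonical order (ascending row
margin), which makes the statistic exactly invariant under relabeling of
the outcome. Zero-count rows/columns are dropped; if fewer than 2×2
remain the statistic is 0 with a warning. The bivariate normal CDF is
evaluated by adaptive quadrature of the single-integral form
`Φ(h)Φ(k) + (2π)^{-1} ∫₀^{asin ρ} exp(−(h²+k²−2hk sin t)/(2cos²t)) dt`,
which is deterministic and accurate to ~1e-10 across the full ρ range
(verified against the closed form at the origin and scipy's
`multivariate_normal.cdf`). The test-suite oracle takes a fully
independent route: dblquad of the density over each cell plus a refined
grid scan in ρ.

**Logistic regression.** `logit P = β₀ + β₁·adi` is maximized by IRLS
(Newton–Raphson on the Bernoulli likelihood), converging when the largest
coefficient step falls below 1e-8, capped at 50 iterations. Wald standard
errors come from the inverse observed information at the optimum; 95% CIs
and p-values are reported on the coefficient scale and the odds-ratio
scale, clearly labeled — no attempt is made to guess the scale of
ambiguous published CI columns. Complete or quasi-complete separation is
detected (saturated fitted probabilities agreeing with the outcome, or a
diverging slope) and raised as an error naming the direction. A single
class in the outcome is an input error. Three pre-specified models are
reported at α = 0.05 with no multiple-testing correction.

**Decile curves.** Risk percentages per ADI decile ([1–10] … [91–100]);
empty bins are reported as missing, never as 0%.

## The synthetic census generator

The generator emulates the statistical structure the analysis needs, not
any real place: ADI marginals (uniform by default; a beta-binomial
`1 + BB(99, a, b)` for skewed cohorts), income affine in ADI with
Gaussian block-group noise and a floor of $2,000 (ACS publishes no
negative medians), MOEs proportional to income, rent and food affine in
income, households assigned to block groups uniformly at random, sizes
1..15 from a configurable pmf, insurance Bernoulli(1 − 0.804).

`cohort_preset()` fixes these knobs to reproduce the published summary
statistics of an underserved Miami-area cohort: beta-binomial ADI
(a = 2.71, b = 1.89; quartiles ≈ 46/61/77), a size pmf with quartiles
1/2/4 and max 15, and income parameters (base $46,000, slope −$280 per
ADI point, block-group noise SD $4,000) calibrated once, by the same grid
search `calibrate_to_quantiles` exposes, so that the generated NSE
quartiles land within ±15% of the published $16,864 / $27,043.50 /
$38,955.75 at n ≥ 5000. Two preset choices deserve explanation:

* **Low out-of-pocket subsistence** (rent ≈ $120/month, food ≈
  $800 + 0.008·income per year). Given the multiplicative equivalence
  scale, the size distribution alone spreads NSE by a factor ≈ 0.79 of
  median income between the quartiles; matching the published median and
  IQR simultaneously then pins median income near $28k and subsistence
  near $2.5k/year. We read this as effective out-of-pocket subsistence in
  a deeply subsidized population (public/assisted housing, SNAP), which
  is also the only reading consistent with the published quartiles under
  the stated imputation conventions.
* **Per-block-group MOE fractions** drawn uniformly from [0.10, 1.70] of
  the income estimate. Real ACS block-group MOEs vary enormously with
  sample size, independently of deprivation; this heterogeneity is what
  lets extreme low-NSE draws occur in mid-deprivation areas, so that the
  rare insured-scenario outcome is only weakly associated with ADI
  (Phi-K ≈ 0.15–0.25) while the common uninsured outcomes remain clearly
  associated (Phi-K ≈ 0.3–0.5) — the qualitative ordering reported for
  real cohorts. A constant MOE fraction instead makes the extreme tail a
  deterministic function of deprivation and inverts that ordering.

What the generator does *not* emulate: spatial autocorrelation between
neighboring block groups, within-block-group income heterogeneity beyond
the MOE draw, correlation of household size or insurance with deprivation,
multi-procedure cost variation, assets/debt, and the joint structure that
produced the cohort's reported 41% poverty rate alongside its NSE
quartiles (under our conventions the preset yields ~15% below the
guideline; reconciling both would require household income to be far more
dispersed than the published quartiles allow). Passing structural tests
therefore show that the *pipeline* reproduces the documented qualitative
findings under a faithful synthetic population — they are not evidence
about any real cohort.

## Numerical and reproducibility choices

* Quantiles use numpy's linear interpolation between order statistics;
  the published-quartile comparisons depend on this convention.
* Percentages are reported to 2 decimals (`100·n/N`), adjusted risks to
  1 decimal; money is written with cent precision, with rounding applied
  only at report boundaries.
* One run seed feeds `numpy.random.SeedSequence(seed)`; stage streams
  are its spawned children in fixed order (0: census generation,
  1: income draws), so stages can be re-run in isolation and a run
  manifest (config + hash + versions) reproduces every output file.
* The calibration search is a deterministic two-stage grid (6×3×3 coarse,
  5×3×3 refinement) over income base/slope/noise, scored by summed squared
  relative quartile error on a fixed evaluation seed; non-monotone
  quantile targets are rejected up front, and failure to reach the
  tolerance raises rather than silently returning the best candidate.
* Default problem sizes — 150 block groups, 5,000 households for
  summary-level runs, 20,000 observations for slope-recovery simulations —
  are the smallest at which the quantities of interest are stable to well
  within the tolerances tested.

## Limitations

The pipeline flags risk for a single procedure at a single average cost;
lengths of stay, complications and indirect costs are out of scope. The
dichotomous rule ignores *degree* of catastrophe (a continuous
strain measure would be a natural extension). Phi-K magnitudes depend on
the binning and on cohort structure, so only orderings — not absolute
values — should be compared across populations. The generator's
block-group economics are reduced-form; none of its parameters should be
interpreted as estimates about any real geography.
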