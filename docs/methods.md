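# Methods

This note records the models implemented in `arcticiso`, their assumptions,
the defaults and why, the synthetic-data design, and the numerical choices
made where the design was genuinely open.

## Temperature response models

**Default MEGANv2.1 short-term activity.** The isoprene activity factor is
the peaked function

γ_T = E_opt · CT2·e^x₁ / (CT2 − CT1·(1 − e^x₂)),  x₁ = CT1/R·(1/T_opt − 1/T),
x₂ = CT2/R·(1/T_opt − 1/T),

with activation energy CT1 = 95 kJ mol⁻¹, deactivation energy CT2 = 230
kJ mol⁻¹ and R = 0.008314 kJ mol⁻¹ K⁻¹. Acclimation enters through
T_opt = 313 + 0.6·(T240 − 297.15) K and
E_opt = 2·e^{0.05(T24−297.15)}·e^{0.05(T240−297.15)}, where T24 and T240 are
the mean air temperatures of the previous 24 h and 240 h. For CT2 > CT1 > 0
the denominator is positive for all real temperatures; the curve equals
E_opt exactly at T = T_opt, rises monotonically below it and falls above it.

At standard acclimation (T24 = T240 = 297.15 K, so T_opt = 313 K,
E_opt = 2) the Q10 of this curve between 25 and 35 °C evaluates to
**2.977**. The widely quoted value for the model is 2.91; the acclimation
state behind that printed figure is not recorded, so this package documents
and reports its own oracle value, which agrees to within 2.3%.

**Sedge response.** Arctic sedges use a purely exponential (Arrhenius)
short-term response with no high-temperature deactivation:
γ = E_opt_sg·exp(C_sg/R·(1/303.15 − 1/T)). Both parameters acclimate to
T240: C_sg = 95 + 9.5·e^{0.53(288.15−T240)} (kJ mol⁻¹), decaying toward the
default CT1 = 95 as the ten-day mean warms, and
E_opt_sg = e^{0.12(T240−288.15)}, growing with it. The two move in opposite
directions by construction — cold-acclimated plants are hyper-sensitive but
low-capacity. Because the exponential has no deactivation term, evaluation
above 313.15 K (40 °C) emits a `RuntimeWarning`: the chamber data show the
exponential regime degrading there, and the published form is simply
extrapolated. The closed-form consequence worth knowing: the 25–35 °C Q10
exceeds 8 exactly when C_sg > ln(8)·R/(1/298.15 − 1/308.15) = 158.8
kJ mol⁻¹, i.e. when T240 < 284.56 K. At T240 = 288.15 K the sedge Q10 is
3.93 — still above the default model's 2.98, but the ecosystem-scale "Q10
over 8" regime is specifically a cold-acclimation phenomenon.

**Willow response.** Willows keep the default peaked curve (same CT1, CT2,
T_opt) with the long-term amplitude replaced by
E_opt_willow = 7.9·e^{0.22(T24−297.15)} — a much stronger previous-day
response than the default 0.05 K⁻¹ rate. The default CT1/CT2/T_opt
parameter set is used unless overridden in the config, since no separate
willow short-term parameterisation is carried here.

## Trailing acclimation means

T24/T240 are arithmetic means over left-open, right-closed windows of
strictly preceding samples: the sample at time t does not contribute to its
own acclimation state ("previous" is read literally). The series must be
regularly sampled; any gap beyond a configurable tolerance raises an error
naming the gap. The first 240 h are flagged missing rather than computed on
shortened windows — shortened windows would silently bias acclimation at
the start of a record, and every downstream consumer (forward model,
fitting, integration) excludes flagged rows.

## Chamber fitting

Arrhenius fits are ordinary least squares of ln(emission) on
x = (1/303.15 − 1/T)/R, so the slope is the activation energy Ea and the
intercept exponentiates to EF30, the emission at 30 °C. Fitting in log
space matches the exponential model, is exact on noise-free data, and is
deterministic — no solver tuning. Steps above `t_max` (default 35 °C,
because the exponential regime degrades beyond 40 °C) are excluded and
counted; non-positive emissions are dropped with a warning. A pre-applied
chamber-blank column, if present in the CSV, is subtracted with negative
results floored at zero (the blank arithmetic is otherwise unspecified).

Q10 from measured steps picks the steps nearest 25 and 35 °C within a 0.5 K
tolerance and applies the exponent correction 10/(T₂−T₁) when the bracket
is not exactly 10 K. Note that an Arrhenius Q10 is not bracket-invariant
even after this correction (the corrected exponent is 10/(T₁·T₂)), so the
bracket is always reported with the number. Per-experiment Q10 values are
summarised as mean ± sd across experiments, not pooled.

**Lag correlation.** For each lag k = 1..15 the predictor is the mean of
the most recent k daily-mean temperatures; Pearson r and its t-test p-value
(α = 0.05) are reported per response (Ea, EF30), plus the lag maximising
|r|. Lag selection is reliable when the response is roughly linear in the
window mean; for strongly curved relations (the exponential Ea–T240 law)
Pearson r is dominated by the extreme-cold experiments and the selected lag
becomes noisy — rank correlation is the better monotonicity statistic
there, and the package's population test uses Spearman for exactly this
reason.

**Acclimation recovery.** With per-experiment (T240, Ea) and (T240, EF30)
pairs, the activation-energy law is fitted by nonlinear least squares for
(amplitude, rate) with the baseline fixed at 95 kJ mol⁻¹ (the warm
asymptote is not identifiable from cold-biased data, so it is imposed), and
the capacity law by OLS on ln EF with a free normalisation at
T240 = 288.15 K. Preconditions: ≥ 3 pairs spanning ≥ 5 K of T240 —
narrower spans leave the exponential rate unidentified.

## Site flux model

The mixture model is linear in the cover-fraction vector, so fitting is a
bounded linear least-squares problem (`scipy.optimize.lsq_linear`):
CF_i ∈ [0, 1] in cover-fraction mode, or E_i ≥ 0 directly in capacity mode
(the default-model variant, which absorbs the unknown emission factor). An
optional sum(CF) ≤ 1 constraint is off by default — fitted fractions need
not fill the footprint. Canopy emission factors are the scalar leaf→canopy
scaling ε* = EF_leaf·5·Cce (the LAI = 5 standard scenario; Cce = 0.3), not
a full canopy radiative-transfer model: the mixture formulation already
externalises canopy effects into Cce·(LAI/LAI_max), and a scalar commutes
with cover-fraction fitting. Cce is applied exactly once (inside ε*);
γ_others is the product of the light/age/CO₂/soil-moisture factors, all
defaulting to 1, with the strict PPFD > 300 µmol m⁻² s⁻¹ filter standing in
for an explicit light response. γ_T uses air temperature unless a leaf
temperature column is supplied. Degenerate designs are rejected: fewer than
10 post-filter observations, or a column-scaled condition number above 10⁸
(two PFTs with proportional basis fluxes cannot be separated; merge them).

R² is reported as the squared Pearson correlation — the scatter-plot
convention, insensitive to affine miscalibration — with 1 − SSE/SST
available via `r2_kind="ss"`. RMSE is in flux units (nmol m⁻² s⁻¹).
Optional daily-mean aggregation is applied before scoring when requested.

## Trend analysis

Annual totals integrate the modelled half-hourly flux trapezoidally over
each calendar year and convert with the isoprene molar mass
(68.12 g mol⁻¹) to mg m⁻² yr⁻¹ — site-scale units; regional Tg-scale
totals require gridded land cover and are out of scope. Years with less
than 95% usable coverage (spin-up, gaps) are dropped with a warning.

The Mann–Kendall statistic S = Σ_{i<j} sign(x_j − x_i) is computed by
direct pair enumeration; tau is the tie-corrected tau-b (equal to
S/(n(n−1)/2) without ties). The p-value uses the exact null distribution of
S for n ≤ 10 without ties and otherwise the tie-adjusted normal
approximation with continuity correction — the standard practice; no
autocorrelation correction is applied, and the choice is this package's,
not asserted as any particular study's. The linear trend is the OLS slope
of annual total on year.

## Synthetic data

The generators define the study conditions for every test; one
`numpy.random.default_rng(seed)` instance drives all draws, so outputs are
bit-reproducible.

*Chamber*: 20 experiments per dataset; ramps 15→40 °C in 5 °C steps at
PPFD ≈ 1000 µmol m⁻² s⁻¹; per-experiment T240 uniform on 278.15–291.15 K
(5–18 °C, the plausible ten-day-mean band of an Arctic tundra summer, wide
enough to identify both exponential rates); emissions from the sedge law
with EF30 base 12.0 nmol m⁻² s⁻¹ (the sedge leaf-level emission factor) and
5% multiplicative lognormal noise. The fifteen prior daily means are drawn
from the population band with ±2 K day-to-day spread and then the most
recent ten are shifted so their mean equals the drawn T240 exactly — the
ten-day window is fully informative, shorter and longer windows only
partially, which is what makes lag identification meaningful.

*Site*: half-hourly records with temperature = 284.15 K summer mean
+ 3 K seasonal and 4 K diurnal (14:00 peak) cycles + an AR(1) daily
synoptic component (coefficient 0.85, innovation sd 1.2 K, interpolated to
half-hourly); PPFD from solar zenith at 68° N with a 1500 µmol m⁻² s⁻¹
clear-sky ceiling; a mild seasonal LAI cycle normalised by its maximum;
flux from the sedge+willow mixture with true cover fractions (0.25, 0.10)
and leaf EFs (12.0, 6.5) nmol m⁻² s⁻¹; additive Gaussian noise with sd
equal to 10% of the mean flux. An optional heatwave injects a block
temperature anomaly. The first ten days lack acclimation and are excluded
everywhere downstream.

What the generators deliberately do not emulate: instrument drift and
calibration error, flux-footprint heterogeneity, gap patterns and u*
filtering, humidity/CO₂ covariates, and real met autocorrelation structure
beyond AR(1). Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise models, not robustness to real-world
data pathologies.

Measured under these conditions (and asserted by the test suite): cover
fractions are recovered with mean absolute error ≈ 0.001 (bound 0.03) over
100 seeds of 60-day records at 10% noise, and the acclimation coefficients
(9.5, 0.53, 0.12) are recovered with the across-seed mean within 0.3% of
truth — and every individual seed within 15% — over 50 seeds of 20
experiments at 5% noise. The recovery bound is read as a bias check on the
mean estimate; both forms hold and both are asserted.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as representative:
60-day half-hourly records (2 880 steps) for site fitting, 20-experiment
chamber populations, 50–200 seeded replicates for recovery and selection
rates, 4-year records for trend pipelines, and exhaustive permutation
enumeration up to n = 8 for the Mann–Kendall oracle.

## Known limitations

- The sedge exponential is extrapolated above 40 °C (warning only).
- The willow short-term curve reuses the default CT1/CT2/T_opt set; a
  dedicated willow parameterisation can be supplied via the config.
- The capacity multiplier E_opt_sg is applied at leaf level; it commutes
  with the scalar canopy factor, so site fluxes are unaffected by the
  placement.
- No eddy-covariance QA/QC, canopy radiative transfer, soil-moisture
  activity (γ_SM = 1) or CO₂-inhibition/leaf-age sub-models (user-supplied
  multipliers, default 1).
- Mann–Kendall assumes serially independent annual values; trend slopes on
  autocorrelated series will overstate significance.
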