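# Methods

This note documents the statistical procedures phenoclim implements, the
choices made where more than one defensible convention exists, what the
synthetic-data generator does and does not emulate, and the numerical
details a user re-deriving results will need.

## Covariates

**Accumulation window.** Covariates accumulate over the `window_days`
(30 or 120) days *strictly before* the observation date; the observation
day is excluded. A record on date *t* therefore needs complete daily
climate on *t−w … t−1*; anything less drops the record with reason
`incomplete climate` in the filter log.

**GDD.** Daily mean temperature is (tmin + tmax)/2. The default floors
each day's contribution at zero — GDD = Σ max(0, T̄ − base), base 5 °C,
no upper cutoff — which is the standard degree-day convention. Because
"negative GDD set to zero" can also be read as flooring the window
*total* of signed anomalies, `gdd_floor="on_total"` implements that
alternative; the two differ only in windows mixing sub- and super-base
days.

**Average precipitation** is the mean daily total over the window
(mm/day). Using a mean rather than a sum makes the 30- and 120-day
covariates directly comparable.

**Daylength** uses the CBM model (Forsythe et al. 1995) with daylight
coefficient p = 0.8333°, the convention of the widely used geospatial
daylength routine (implementation verified against it to < 1e-9 h).
The acos argument is clamped to [−1, 1], so polar day/night yield
exactly 24/0 h. Day of year is wrapped into 1–365.

**Confirmed absences.** An absence is kept only if the whole plant was
visible; partial-plant and uncertain absences are uninformative (flowers
could be out of frame) and are dropped. Presences are kept at any
visibility. The filter logs one count per reason and is idempotent.

**Scaling.** Predictors are z-scaled (mean 0, sample sd with n−1,
matching the conventional scaling function in this field's ecosystem)
using statistics from the *training* rows only. Test and anomaly rows
are pushed through the frozen training transform; a distribution shift
in new data then shows up as a non-zero scaled mean, by design. A
zero-variance column raises an error naming the column.

## Model families

**Seasonal curve.** Flower presence vs day of year is smoothed with a
periodic penalized logistic regression: K = 12 cyclic cubic B-spline
basis functions on equally spaced knots over a 365.25-day period, a
second-order difference penalty with wrap-around (null space = constant,
so infinite smoothing flattens to the overall rate on the logit scale),
penalized IRLS with step-halving, and λ chosen by AICc over 25
log-spaced values in [1e−3, 1e5] with edf = tr[(X′WX + λS)⁻¹X′WX].
Periodicity of value and first derivative at the year boundary is
structural (every basis function is C² across the wrap), not a fitted
constraint. This reproduces cyclic-spline GAM behaviour without a full
GAM engine (tensor smooths and REML are out of scope).

**Interaction GLMs.** The candidate ladder crosses daylength degree
(linear vs orthogonal degree-2 polynomial) with interaction order (none,
all pairwise, full three-way), giving six specifications from 4 to 12
design columns; the 12-column model is
intercept + GDD + precip + poly₁ + poly₂ + five pairwise products + two
three-way products. The polynomial basis is orthonormal (Forsythe
three-term recurrence, the algorithm behind the usual `poly()`
transform), fitted on training data and frozen for prediction, which
avoids the raw-polynomial collinearity that would otherwise dominate the
design.

**Fitting** is Newton/IRLS on the Bernoulli log-likelihood with
step-halving (the log-likelihood is non-decreasing across iterations),
max 50 iterations, convergence at max |score| < 1e−8. Standard errors
come from the inverse Fisher information. Perfect separation is detected
two ways — collapsing working weights/diverging coefficients during
iteration, or fitted probabilities within 1e−3 of the response
everywhere — and is reported as a warning with `converged=False` rather
than silently returning huge coefficients. AIC = −2ℓ + 2k,
AICc = AIC + 2k(k+1)/(n−k−1); both McFadden and Nagelkerke pseudo-R² are
computed and labelled explicitly (reports that print a single unlabelled
"R²" are ambiguous between the two).

**Collinearity screen.** Candidates whose *driver* columns (the main
effects, with daylength expanded to its polynomial columns) have any
VIF > 5 are excluded before fitting, where VIF_j = 1/(1−R²_j) from
regressing column j on the other drivers plus an intercept; exact
collinearity reports +∞. The screen is deliberately applied to the
drivers, not to interaction columns: products of mean-zero predictors
carry mechanically inflated per-column VIFs even when the drivers are
near-orthogonal (the reason generalized VIF exists), so screening
product columns would veto every interaction model regardless of data
quality. Generalized (per-term) VIF is out of scope.

**Selection** ranks screened candidates by AIC or AICc, reporting ΔIC
and Akaike weights w_i = exp(−Δ_i/2)/Σexp(−Δ_j/2); ties break toward
fewer parameters, making the result independent of candidate order.
Cross-validated selection defaults to AICc (small training folds); the
final full-data fit defaults to AIC; both are config flags. The ΔAIC
quoted for a final model is criterion(second-best) − criterion(best).

## Validation and thresholds

Anomalous-period rows are separated first and are refused — by a
hard check, not convention — from scaler fitting, polynomial-basis
fitting, model selection and threshold derivation. The normal-period
rows are split 75/25 ten times (independent uniform splits from a
spawned seed sequence); per replicate, all transforms and selection are
re-fit on the training fold and AUC is computed on both folds through
the frozen transforms. AUC is the Mann–Whitney concordance
P(score₊ > score₋) + ½P(tie), computed with midranks. The accumulation
window (30 vs 120 days) is chosen by higher mean test AUC, then the
final model is selected and fitted on all normal-period rows with that
window.

Classification uses "presence if probability ≥ threshold". Thresholds
derive from the final model's calibration predictions on the full
normal-period set (the anomaly test applies a finished model, so
calibration-set thresholds — not per-fold ones — are the coherent
choice; the alternative is noted as an open reading):

- **MaxKappa**: Cohen's κ evaluated at every achievable cutoff (unique
  scores, adjacent midpoints, and 0/1); ties break toward the smallest
  cutoff, making the result deterministic.
- **LPT**: the minimum calibration presence score — zero omission on
  calibration by construction.
- **LPT 5%**: the lower empirical 5% quantile of presence scores
  without interpolation, so ≥ 95% of presences stay classified present.

Anomaly rows are scored with the final model and classified at each
threshold; the report gives overall accuracy, commission = FP/(FP+TN)
and omission = FN/(FN+TP) as percentages (the SDM convention; an
anomaly set lacking absences or presences reports the undefined rate as
NA with a warning). Lowering a threshold can only raise commission and
lower omission, so LPT (the lowest cutoff) always bounds the others'
commission from above.

## The synthetic generator

The generator supplies the statistical structure the analysis assumes,
with known truth for recovery tests:

- **Temperature**: daily mean = annual sinusoid (mean 18 °C, amplitude
  10 °C, peak day 200) + N(0, 2 °C); tmin/tmax = mean ∓ 6 °C. These
  defaults give a Mojave-like thermal year at 33–37° N.
- **Precipitation**: Bernoulli wet day (p = 0.25) × exponential
  intensity. The unconditional daily mean follows a cosine peaking
  mid-January between a winter mean (1.5 mm/day) and a summer mean
  (0.3 mm/day); the cosine's amplitude is calibrated so that the Dec–Feb
  and Jun–Aug *window averages* equal the configured means (a cosine
  through the configured values as extremes would miss the summer window
  average by ~45%). Zero-inflation and the winter peak mirror desert
  rainfall; the 15%-accuracy Monte-Carlo check on these means is run on
  averages over several replicates because daily totals are heavy-tailed.
- **Anomalous season** (default 1 Sep 2018 – 28 Feb 2019, mirroring an
  unusually cold and wet fall–winter): temperature offset −4 °C,
  precipitation ×2.5 inside the interval.
- **Flowering**: sites and admissible dates sampled uniformly; the logit
  is x·β on the same scaled 12-term design the analysis fits (scaler and
  polynomial basis fitted on the sampled records), plus δ·1[anomalous].
  The default β is the package's reference strong-three-way truth:
  flowering favoured by cool conditions and mid-length days with a
  context-dependent precipitation response, at an overall normal-season
  prevalence of ~0.16 and a spring peak — the regime the analysis is
  designed for. δ defaults to −2 (out-of-season blooms suppressed
  relative to what climate suitability alone predicts, the signature the
  anomaly test looks for; δ = 0 makes anomalous flowering follow the
  normal-season response). Because the polynomial columns are
  unit-norm, the daylength-term effect size implied by a fixed β scales
  with 1/√n; the defaults are calibrated for n in the low thousands.
- **Annotations**: 15% of records are marked partial-plant and 5%
  uncertain, exercising the confirmed-absence filter. Every record
  carries its latent true probability.

Not emulated (and therefore not demonstrated by passing tests):
photographer bias toward flowering plants, spatial correlation or
elevation structure in climate, temporal clustering of observation
effort, and annotation error. Real-data performance can differ most
where those features interact with the confirmed-absence rule.

## Problem sizes and runtime

Default study conditions are 12 sites × 4.5 years of daily climate and
3000 observations (~2200 normal-period rows after filtering), with 10 CV
replicates × 6 candidates × 2 windows; a full pipeline run takes a few
seconds on one CPU. Recovery experiments in the test suite use n = 5000
(coefficients), n = 3000 (selection), and 10-seed repeats for the
window, null and anomaly-monotonicity experiments.

## Known limitations

- The cyclic smoother fixes its basis size (12) and chooses only λ;
  very sharp seasonal features would need more basis functions.
- The VIF screen addresses driver collinearity only; it does not
  penalize the (expected, benign) correlation between a product term
  and its parents.
- Threshold derivation on the full calibration set slightly favours the
  final model relative to deriving them per CV fold; with n ≈ 2000
  calibration rows the difference is small.
- AUC, κ and the thresholds treat observations as exchangeable; no
  spatial or temporal block structure is respected in the splits.
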