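# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limits of what the tests demonstrate.

## Scope and design

The package reimplements an integrated counterfactual assessment of a
biofuel mandate: a persistent crop-price shock propagating through crop
rotations and cropland extent into nutrient, water-quality, and
greenhouse-gas outcomes, ending in a revised fuel carbon intensity.  The
econometric components are sklearn-style estimators (`VARPriceModel`,
`RotationTransitionModel`, `CRETransitionModel`) because they are genuinely
fit/predict-shaped; the accounting stages are deterministic arithmetic and
are plain functions.  The process-based agroecosystem simulator of the
original workflow is represented by a response table of per-rotation and
per-cover indicator rates; the package implements exactly the weighting
scheme that turns probability and extent deltas into indicator deltas.

## Price counterfactual

Log prices follow a VAR(1).  The policy is a persistent demand shock:
the generator adds a constant log-price step `s` (default `ln 1.3` for corn,
`ln 1.2` for the composite alternative crop) to the BAU path from the policy
year on, with identical innovations in both paths, so the generating
observed/BAU ratio is exactly `e^s` in every post-policy year.

Estimation is equation-by-equation OLS with a step dummy at the known policy
onset.  Fitting across the break without the dummy would bias the lag
matrix, so the dummy is always included when an onset year is supplied; its
coefficient doubles as a data-driven per-period shock loading.  The BAU path
subtracts the cumulative response `d_t = A d_{t-1} + λ` (λ applied each
period from onset).  Two loadings are supported:

* *config*: `λ = (I − Â) s` converts the configured long-run step through
  the fitted dynamics (pipeline default; reduces exactly to BAU ≡ observed
  when `s = 0`);
* *estimated*: the step-dummy coefficient (used by the bootstrap-coverage
  studies, where the shock must be recovered from data).

The constant-step generating process and the recursive removal differ in
the onset year only (the recursion reaches `s` geometrically); this
transient is visible as a mild downward tilt of window-mean impacts on short
series and vanishes with series length.  Uncertainty uses a residual
moving-block bootstrap (block length `≈ n^{1/3}`), rebuilding the series
under the fitted dynamics and refitting; intervals are percentile.  The
bootstrap-coverage study in the test suite therefore uses a longer synthetic
series (1950–2016) so that VAR asymptotics apply; at the default 17-year
span point estimates remain approximately unbiased but percentile intervals
undercover, which is a documented small-sample limitation, not a defect.

Impacts are per-crop window means of `100·(observed/BAU − 1)` over the
post-policy years, divided by the demand increment (5.5 BGY) for the
per-BGY normalization.

## Crop rotations

Eligibility screens mirror the field-database construction: fields above
15 acres (6.07 ha), in regions with cropland share > 20%, corn share of
cropland > 10%, and priced share of non-corn cropland > 50%.  Thresholds
are strict inequalities; a zero threshold disables its screen so that an
all-zero criteria set retains everything.

Two crop classes are used ({corn, other}) because the transition models
condition only on corn vs non-corn; the alternative crops are collapsed
into a composite price index.  Per stratum, two logits with covariate
`log(p_corn/p_other)` give `p_cc` and `p_oc`.  Perfect separation (a
single-outcome cell) falls back to pooled coefficients and is flagged.

Rotation categories come from the stationary pair-state distribution of the
fitted chain: continuous corn `π p_cc`, rotation `π(1−p_cc) + (1−π)p_oc`,
continuous other `(1−π)(1−p_oc)`, with `π = p_oc/(1−p_cc+p_oc)`.  This
makes the three shares sum to one and the two corn categories sum to `π`
by construction, so the corn-area decomposition is exactly additive.  The
degenerate pair `p_cc = 1, p_oc = 0` (two absorbing states) is rejected
because the long-run state depends on initialization.

BAU prices for the delta step deflate the post-policy price ratio by the
constant estimated impacts (`x_bau = x − log((1+Δcorn)/(1+Δother))`),
i.e. a constant shock applied to all policy years; deltas are annual means
over the policy window, aggregated over field areas per stratum.

## Cropland extent

Four directed transitions (pasture→crop, crop→pasture, crp→crop at contract
expiry, crop→crp in sign-up years) are fitted per land resource region as
logits on `[1, return gap, soil index, parcel time-mean return gap]`.  The
time-mean term is the correlated-random-effects device; the test suite
demonstrates on synthetic data that the CRE estimator recovers the
generating returns coefficient while the pooled logit without time-means is
materially biased.  Regions with no at-risk rows are skipped with a
warning; unidentified designs (e.g. returns constant over parcels and time)
and separation fall back to the pooled fit and are flagged.

Predictions are population-averaged probabilities (logit evaluated at
covariates plus time-means, no numerical integration over the residual
parcel effect), because deltas of averaged probabilities are what aggregate
to hectares.  BAU returns deflate crop returns by the price impact at fixed
alternative returns and fixed time-means.  Eight annual transition steps
are predicted starting with policy-year → policy-year+1.  Attribution gives
every observed converted parcel in a region the clamped fraction
`min(max(Δ/observed, 0), 1)`, conserving area; avoided-abandonment weights
are per-parcel `p(BAU) − p(factual)` for the abandonment directions, which
sum (× expansion factor) to the aggregate avoided hectares identically.

## Environmental accounting

County nutrient totals are inverted to per-crop rates via
`base = total / Σ_c k_c a_c` with ratio vector `k` (corn ≡ 1); the synthetic
county totals are constructed as exact linear combinations so the inversion
round-trips to machine precision.  Manure and synthetic fertilizer are
merged into single N and P totals.

Indicator deltas: rotation side `Σ area · Δp(category) · rate(category)`,
extent side `Σ weight · area · (rate_cropland − rate_prior_cover)`, with
avoided-abandonment parcels contributing the same difference (counterfactual
cover configurable, default grassland).  Units are centralized in
`rfsluc.units`: applications and nitrate in Gg, P runoff in Mg, erosion in
Gg (rates in Mg/ha), N₂O and carbon in Tg CO₂e.  Combined = rotation +
extent exactly; `%Δ from BAU` divides by a BAU baseline (for the synthetic
scenario, factual level minus combined delta; zero baselines yield flagged
nulls); `%Δ per BGY` divides further by the demand increment.

## GHG and fuel intensity

* N₂O: `flux(N) = exp(c0 + c1 N)` kg N₂O-N/ha/y with defaults
  `c0 = −0.8`, `c1 = 0.0116` (≈2.6 kg at 150 kg N/ha, convex in N, in the
  range of field-calibrated exponential response models); conversion
  44/28 × GWP 265.  Because each field occupies one rotation category at a
  time, category fluxes mix linearly in probabilities.
* Conversion carbon: full biomass loss and 25% soil-organic-carbon loss by
  default (both configurable in [0, 1]), × 44/12, with an optional additive
  methane term per hectare.
* Forgone sequestration: grassland carbon response `A(1 − e^{−kt})` with
  `A = 12 Mg C/ha`, `k = 0.07/y`, horizon 15 y (one CRP contract,
  ≈0.5 Mg C/ha/y early rates).  Carried at its committed 15-y value.
* Amortization: the committed total is spread over 30 y, divided by
  20.8 × 10⁹ L/y and 21.46 MJ/L.  Annual N₂O is added un-amortized when the
  intensity includes it.
* Substitution: `revised = published_total − published_domestic_luc +
  new_domestic`, affine with slope one; percent change is relative to
  93.1 g CO₂e/MJ gasoline.  The shipped published records include a program
  whose land-use-change entry combines domestic and international terms; it
  is reported but not revised, since subtracting a combined term would not
  isolate the domestic component.

## Synthetic study system

The generator emulates: a 2-crop log-price VAR with the persistent policy
step; ~20,000 fields (default) in abstract region×soil strata with
log-normal areas truncated at 6.07 ha and price-responsive crop sequences;
~8,000 survey points with expansion factors, returns covariates with
persistent parcel components (so parcel effects can be made
returns-correlated with `γ = 0.5`), CRP sign-ups every 2 y and 15-y
contracts; county nutrient totals that are exactly invertible; log-normal
response rates and carbon stocks.  One named child stream of the master
seed per generator (offsets 1–6) lets each module be regenerated
independently and makes every output byte-reproducible.

What it does **not** emulate: real geography and spatial correlation,
multi-crop price cross-elasticities, yield responses, measurement error in
land-cover maps, returns constructed from yields and costs, or any
process-based biophysics.  Passing tests therefore demonstrate internal
consistency and estimator correctness under the stated generating models,
not agreement with real field data; the published headline magnitudes enter
only as fixture inputs to the accounting layer.

Default sizes (20,000 fields, 8,000 parcels, 1,000 propagation draws — the
acceptance script uses 200 draws; the coverage studies use 4,000-field
panels with 300 draws and 200 price replicates at 100 bootstrap reps) were
chosen as desk-scale problems where the recovery tolerances (3 SE; 92–98%
coverage bands) are informative.

## Numerical choices

* Logit link throughout; GLM/IRLS fits via statsmodels with coefficient
  covariances retained for propagation.
* Quantiles: numpy's default linear interpolation (type-7); draws 1..1000
  give [25.975, 975.025] at the 2.5/97.5 percentiles.
* `π` uses a `1e-12` floor on `1 − p_cc + p_oc` in vectorized paths; the
  scalar API rejects the doubly-absorbing case explicitly.
* Constant (zero-variance) lag columns in the VAR design get exact zero
  slopes rather than a least-norm split; any other rank deficiency is an
  error.
* CI-of-CI behavior: propagation quantiles are consistent as draws grow;
  small draw counts (≲50) give visibly unstable interval endpoints.
* NaN propagation draws are excluded from quantiles with their count
  reported.

## Known limitations

* Price-impact uncertainty is excluded from the Monte Carlo propagation by
  design (held at point estimates); rotation and extent coefficient draws
  are propagated jointly but independently of each other.
* The per-period-loading counterfactual understates the constant-step
  generating gap in the onset year (geometric approach to the long-run
  step); percentile bootstrap intervals undercover on very short series.
* Attribution clamps regional fractions to [0, 1]; predicted conversion in
  regions with zero observed conversion is dropped with a warning.
* Response-table rates are time-invariant; indicator deltas therefore scale
  exactly linearly in probability and extent deltas.
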