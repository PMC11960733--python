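# Methods

`baycarb` implements the analysis chain used to quantify long-term
dissolved-oxygen (DO) and pH change in a nutrient-reduced, warming estuary
monitored by a fixed-site sensor network: QA/QC of raw sensor series,
de-seasonalized monthly-anomaly trend estimation, carbonate-system
reconstruction from pH and salinity, a two-endmember conservative mixing
model, and driver-attribution budgets. This note records the models, the
defaults and why, the numerical choices, and what the synthetic test bed
does and does not establish.

## Sensor ingest and units

Network files are delimited text, one row per timestamped reading per
station and layer (surface/bottom), with blank fields meaning "not
measured" (distinct from zero — relevant for chlorophyll). Physical
validity windows (T in [-3, 40] degC, S in [0, 40], DO >= 0 mg/L, pH in
[5, 10] NBS) are enforced on ingest; rows failing them are counted and
reported, never silently dropped. Duplicated station/layer/timestamps keep
the first reading. Timestamps are treated as local wall clock and days are
calendar dates: the analysis operates at daily-and-coarser resolution, so
time-zone and DST subtleties are below its floor.

DO is converted from mg/L to umol/kg reading-by-reading at in-situ
temperature and salinity,

    DO[umol/kg] = DO[mg/L] * (1000 / 31.998) / rho(T, S),

with rho from the EOS-80 surface-pressure equation of state (UNESCO 1983;
Millero & Poisson 1981), verified against the published check values to
5e-5 kg/m^3. Mass-specific units make the quantity conservative under
heating, so solubility and biological effects can be separated later. The
density standard is a package-level choice; the conversion is exactly
invertible.

## QA/QC: daily means and the iterative IQR row cascade

Raw readings are collapsed to daily means (a minimum reading count per
parameter-day is configurable, default 1). A day is an outlier for a
parameter when its value falls outside

    [Q1 - 1.5 IQR, Q3 + 1.5 IQR],

with quartiles estimated by linear interpolation of order statistics
("type 7", configurable) per station, per layer, per parameter, over the
full multi-year daily series. Because brief extreme events (episodic
blooms, transient hypoxia) contaminate all simultaneously measured
parameters, a flagged day's entire row is removed when any one of
temperature, salinity, DO or pH is flagged; fences are then recomputed on
the survivors and the screen repeated to a fixed point (cap 50 passes;
real and synthetic series converge in well under 15). Chlorophyll is never
screened — the bottom layer has no chlorophyll sensor, and filtering only
the surface would bias the layers against each other. A day missing a
parameter is retained and simply not tested on it. The removed fraction is
an emergent diagnostic reported in the JSON outlier report, not a target.

## De-seasonalized anomalies and trends

Monthly means of clean daily values feed a climatology: the multiyear mean
of each calendar month per station/layer/parameter (minimum contributing
years configurable, default 3). Subtracting it gives monthly anomalies,
which average to zero per calendar month by construction. Anomalies are
averaged unweighted across an analysis station set — by default excluding
the river-dominated low-salinity station — to form bay-wide series;
stations silent in a month drop out of that month's denominator.

Trends are ordinary least squares of the bay-wide anomaly on decimal time
(year + (month - 0.5)/12; month-centered so the axis is unbiased), with a
two-sided slope p-value and 95% CI. The Durbin-Watson statistic is
attached purely as an autocorrelation screen — its p-value uses the
normal approximation DW ~ N(2, 4/n), adequate for screening — and is
never used to adjust the inference; monthly anomalies in this setting are
near-white, and the synthetic test bed is constructed to respect that (see
below). A summer-only mode (months 6-9) supports seasonal robustness
checks. Bivariate anomaly regressions (e.g. DO vs temperature, pH vs DO)
run on matched (year, month) pairs, with surface, bottom, mean-of-layers
and pooled modes.

## Carbonate system

Speciation is implemented from first principles at surface pressure on the
total hydrogen-ion scale. The alkalinity balance is

    TA = [HCO3-] + 2[CO3 2-] + [B(OH)4-] + [OH-] - [H+]free - [HF],

with phosphate and silicate set to zero (not measured by the network;
minor in these waters). Constants: carbonic acid from Lueker et al.
(2000), borate from Dickson (1990b), bisulfate from Dickson (1990a), water
from Millero (1995), fluoride from Perez & Fraga (1987), CO2 solubility
from Weiss (1974), total borate from Uppstrom (1974) — the default set of
the standard CO2-system calculators, and each formulation verified against
published pK values at T=25, S=35 to 1e-4. The constants-set name is
recorded in every output. pCO2 is fCO2 divided by the Weiss virial
fugacity factor.

Any two of {TA, DIC, pH, pCO2} determine the rest. The implicit direction
(TA, DIC) -> pH uses vectorized bisection on pH in [3, 12], where the
alkalinity residual is monotone, iterated to 1e-12 pH — unconditionally
convergent at estuarine TA:DIC ratios, and fast enough to speciate
multi-year daily series in bulk. Closed forms cover the explicit pairs.
Round-trip closure is maintained to well below 1e-6 pH; the test suite
cross-checks against an independently coded speciation oracle.

Sensor pH is NBS; speciation is total-scale. The two are related by a
constant offset, NBS = total + 0.13 — the activity-coefficient conversion
cannot be computed rigorously from what a glass electrode in an estuary
reports, and the constant-offset convention is the established practice
for these data. The temperature sensitivities at the typical bay state
(T=17 degC, S=30, TA=2037, DIC=1915 umol/kg) are dpH/dT = -0.0147 per
degC and +4.1%/degC for pCO2 at fixed TA and DIC. The often-quoted ~4.2-
4.3%/degC for pCO2 is an empirical open-ocean figure; thermodynamic
calculation with the Lueker constants gives ~4.1% across both estuarine
and open-ocean states, and that computed value is what the package
reports.

TA and DIC are tied to salinity by the Narragansett Bay regressions
(TA = 51.99 S + 477.62; DIC = 50.59 S + 397.65 from discrete bottle
samples, with the 50.60 S + 397.5 printing and the sensor-derived
52.05 S + 382.64 refit also registered). DIC calculated from salinity-
estimated TA and measured pH carries the sensors' uncertainty: Monte-Carlo
propagation (independent normal errors, sd 10 umol/kg in TA and 0.1 in
pH, 5000 draws per condition, seeded) over a grid of bay conditions
(S = 20-32 step 2, pH 7.6/7.9/8.2, T = 17) gives a mean DIC standard
error of ~34 umol/kg, under 2% of absolute DIC — small against the
>600 umol/kg mixing-driven DIC range in this salinity band.

## Two-endmember mixing and attribution budgets

Because TA is conservative and DIC is conservative absent biology and gas
exchange, the salinity regressions define the carbonate chemistry of any
mixture of the freshwater (S=0, TA:DIC = 1.2) and saline (S=33,
TA:DIC = 1.06) endmembers. Speciating (TA(S), DIC(S)) along a salinity
grid at the bay mean temperature (17 degC) yields the pH mixing curve —
the pH expected from water-mass mixing alone, monotonically decreasing in
salinity under these endmembers because the TA:DIC buffer ratio falls.
The default grid step is 0.1 PSU: the curve is strongly curved at low
salinity, and this spacing keeps linear-interpolation error below 1e-4 pH
everywhere (a 0.5-PSU grid leaves ~1.7e-3 error near S=0). The freshwater
DIC endmember is the curve's sensitive input; a +/-10% perturbation
(~40 umol/kg) shifts the curve visibly, most strongly below S~25, and the
perturbation machinery returns paired base/perturbed curves for envelope
plots.

Observed pH is compared to the curve after isochemical temperature
adjustment: speciate at in-situ T with TA(S) and measured pH (converted to
total scale), then re-solve at 17 degC holding TA and DIC fixed. The
method of adjustment is a package choice; it is the standard
thermodynamic one. Deviations from the curve isolate non-conservative
processes: bloom DIC drawdown raises pH above it, respiration pushes it
below.

Attribution budgets are linear decompositions. For DO: temperature term =
(DO-per-degC slope) x warming rate, salinity term likewise, biological
residual = observed - (temperature + salinity). For pH, four processes:
mixing (salinity trend x pH-salinity slope), respiration change
(biological DO rate x pH-DO slope), warming (rate x solver dpH/dT), and
atmospheric CO2 uptake, an exogenous open-ocean literature rate (default
-0.0015/yr, range -0.001 to -0.002) rather than something computed from
CO2 records. Slopes default to a frozen "paper coefficients" profile
(DO: -3.7 umol/kg/degC, -0.98 umol/kg/PSU; pH: +0.0163/PSU,
+0.00156 per umol/kg DO) for reproducing the published arithmetic, but any
`regress_anomalies` output can be substituted. Budgets report rate and
cumulative forms; the residual is always observed minus the sum of terms.

## Synthetic monitoring network

The generator produces a ten-station, two-layer, fifteen-year network
(two stations year-round, the rest May-October, one river-influenced
low-salinity station excluded from bay-wide averages by default) with
known ground truth, so every pipeline stage is testable without external
data. Temperature, salinity and surface chlorophyll are mean + two
seasonal harmonics (annual + semiannual) + linear trend + noise; salinity
additionally carries a +/-2 PSU slow excursion with exactly two full
periods over the record (decade-scale freshening/drought variability that
projects to zero onto the trend axis). DO is the solubility of the
generated T and S plus a biological deviation — chlorophyll-coupled in the
surface, respiration-like offset in the bottom, plus a temperature-coupled
biological term. pH is obtained by speciating TA(S) with DIC =
conservative DIC(S) minus a DO-coupled biological perturbation plus an
AR(1) "biogeochemical" DIC noise term, so the generated (T, S, TA, DIC,
pH) tuples close the carbonate system exactly by construction at daily
cadence. Sub-daily cadence replicates the daily truth with white reading
noise on the reported sensor values (the analysis consumes daily means;
tidal realism is out of scope). Outliers are injected as fence-exceeding
spikes (one IQR beyond the Tukey fence by default) at a configurable
parameter-day rate, timestamps recorded.

Noise is two-scale: a daily AR(1) component (rho = 0.75 for most
parameters, 0.5 for chlorophyll) split into a bay-wide shared forcing felt
by every station and an independent per-station part, plus white reading
noise. Daily-scale memory makes monthly anomalies near-white, which is
both what the network's monthly anomalies show under the Durbin-Watson
screen and the regime in which plain OLS confidence intervals are
calibrated; monthly-scale red noise would invalidate the uncorrected OLS
inference the trend method deliberately uses. Noise amplitudes were chosen
once to give bay-wide monthly anomaly spreads comparable to the observed
series (T ~0.5 degC, S ~0.5 PSU, DO ~6 umol/kg, pH ~0.02, Chl ~1 ug/L).

Requested trends are injected exactly: the generator decomposes each total
DO and pH trend through locally averaged partial derivatives (solubility
with respect to T and S over the seasonal envelope; pH with respect to S,
T and DIC) and assigns the residual linear rate to the biological DO term
and the DIC trend term respectively. All calibrated coefficients, trend
truths, effective couplings and injected-outlier timestamps go to a JSON
truth ledger; identical seeds give bit-identical output. The default
truths are the observed bay rates: surface DO -0.69 and bottom DO
+0.43 umol/kg/yr, bottom pH +0.0021/yr, surface chlorophyll
-0.26 ug/L/yr, warming 0.020 (surface) and 0.041 (bottom) degC/yr,
salinification 0.0363 PSU/yr.

What the test bed shows: the full chain (ingest -> QA/QC -> climatology ->
bay-wide anomalies -> OLS) recovers each injected trend with 95% CIs that
cover truth in >= 90% of 50 seeded replicates, catches >= 95% of injected
outlier days, and reproduces injected couplings when the generator
isolates them. What it does not show: performance under sensor drift,
fouling, calibration steps or gaps (no drift model); under spatially
structured gradients beyond station offsets; or under the real bay's
biologically dominated pH-salinity covariance — in the synthetic bay the
interannual salinity excursion imposes the conservative-chemistry
(negative) pH-S anomaly relation, whereas the real estuary shows a
positive relation because freshwater events bring heterotrophy. For the
same reason the pH-DO anomaly regression on the full profile recovers the
injected coupling plus a real mixing covariance; the coupling-recovery
tests disable the excursion to isolate the injected value.

## Numerical and degenerate-input choices

* Quartiles: numpy "linear" (type 7); configurable. Fewer than 4 finite
  values is an error for fence computation; within the cascade such a
  parameter is simply skipped.
* Identical values give IQR = 0 and degenerate fences equal to the value:
  nothing is flagged.
* pH bisection: fixed iteration count to interval < 1e-12, no derivative
  use; unbracketed roots (non-physical TA/DIC) raise with a count of
  offending inputs.
* Trend fits require >= 24 months and a non-degenerate time axis; a
  perfect fit reports DW = NaN rather than dividing by zero.
* Monte-Carlo DIC propagation fails loudly if more than 1% of draws fail
  speciation.
* Endmember perturbations are capped at +/-50% of the freshwater DIC
  intercept; mixing-curve grids must be strictly increasing within
  [0, 35].
* Observations outside the mixing-curve grid get NaN deviations and are
  counted, not extrapolated.

## Problem sizes

Default synthetic runs use daily cadence (the pipeline's native
resolution; sub-daily expansion is available and tested at small scale),
ten stations and fifteen years — about 66,000 station-layer-days per
realization. The replicated trend-recovery property uses 50 such
realizations. The Monte-Carlo error propagation uses 5000 draws per
condition over 21 conditions.

## Known limitations

* The NBS/total pH-scale link is a constant 0.13 offset; no
  ionic-strength dependence.
* No nutrient alkalinity, no pressure dependence, no CaCO3 saturation
  states.
* The atmospheric-acidification budget term is a literature constant, not
  a computed flux.
* The Durbin-Watson p-value is a large-n normal approximation.
* The generator has no hydrodynamics, no tidal variability, and no
  spatial correlation structure beyond the shared bay-wide forcing.
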