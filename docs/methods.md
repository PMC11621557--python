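# Methods

## Scope and model

`soilrisk` assesses heavy-metal-contaminated soil along the standard
environmental-health chain: measured concentration → contamination index →
exposure dose → non-carcinogenic and carcinogenic risk → uncertainty
(Monte Carlo) → spatial surface (IDW). The measured input is a soil-survey
table: one row per site with WGS84 coordinates and per-metal
concentrations in mg/kg. All other quantities are literature constants
held in three registries (geochemical backgrounds, exposure profiles,
toxicity values), every one overridable through a flat dotted-key YAML
config (`exposure.adult.BW: 65`).

## Contamination indices

- `igeo(c, b) = log2(c / (1.5 b))`. The 1.5 factor absorbs natural
  background variation. Classes: Igeo ≤ 0 → 0, (k−1, k] → k for k = 1…5,
  \> 5 → 6. Igeo is undefined (a distinct error class) for c ≤ 0.
- `cf = c / b`, binned < 1 low, [1, 3) moderate, [3, 6) considerable,
  ≥ 6 very high. The boundary CF = 6 is assigned to "very high" so the
  partition is total.
- `pli` = geometric mean of a site's CFs, computed as `exp(mean(log cf))`
  for stability. Metals unmeasured at a site are excluded with n reduced;
  a measured CF of exactly 0 makes the geometric mean degenerate, so that
  site's PLI is reported missing with a warning rather than as 0 — a
  silent zero would masquerade as "no pollution".

## Exposure doses

Chronic daily intakes per route (mg/kg/day), linear and homogeneous in the
concentration:

    ingestion   c · IR_ing · EF · ED / (BW · AT) · 1e-6
    dermal      c · SA · AF · ABS · EF · ED / (BW · AT) · 1e-6
    inhalation  c · IR_inh · EF · ED / (BW · AT · PEF)

The 1e-6 converts mg soil → kg soil; inhalation instead divides by the
particle emission factor PEF (m³/kg), which converts soil concentration to
airborne dust concentration.

Default exposure profiles (all config-overridable):

| parameter | adult | teenager | child | units |
|---|---|---|---|---|
| IR_ingestion | 100 | 150 | 200 | mg soil/day |
| IR_inhalation | 20 | 15 | 10 | m³/day |
| EF | 365 | 365 | 365 | days/year |
| ED | 35 | 15 | 3 | years |
| BW | 70 | 35 | 15 | kg |
| SA | 6600 | 5000 | 2800 | cm² |
| AF | 0.07 | 0.2 | 0.2 | mg/cm² |
| ABS | 0.001 (0.03 for As) | — | — | fraction |
| AT | ED × 365 | — | — | days |
| PEF | 1.36 × 10⁹ | — | — | m³/kg |

Design notes on these defaults:

- **Averaging time.** AT defaults to ED × 365, i.e. risk is averaged over
  the exposure window itself; with EF = 365 this makes the ingestion dose
  reduce to `c · IR / BW · 1e-6` and renders it independent of ED (a
  property the tests assert). AT is an independent knob: a cancer-endpoint
  convention of a 70-year lifetime is `exposure.<age>.AT_days: 25550` in
  config, not a code change.
- **AF and ABS** are the USEPA-conventional residential soil-contact
  defaults (adherence 0.07 adult / 0.2 child-teen mg/cm²; absorption
  fraction 0.001 generic, 0.03 for arsenic, applied per metal by the risk
  pipeline). They are generic screening values, not site measurements.
- **PEF** is the standard USEPA particle-emission screening value.
- **IR_inhalation** values are interpreted as m³/day, the standard unit
  for age-stratified inhalation rates.

## Risk

HQ = DI/RfD, HI = Σ HQ over metals within one route and age group,
CR = DI × CSF. Bands: CR ≤ 1e-6 negligible, (1e-6, 1e-4] acceptable,
\> 1e-4 unacceptable — boundary values deterministically assigned.

The shipped toxicity registry covers As, Cd, Fe, Hg, Ni, Pb, Zn with
route-specific oral/dermal RfDs and oral/dermal/inhalation CSFs where
established (e.g. As: RfD_ing 3e-4, CSF_ing 1.5, CSF_inh 15.1). No
inhalation RfD ships by default; a (metal, route) pair without a value is
reported **not assessed** (NaN with an explicit band label), never imputed
and never silently dropped — doses are still reported for such pairs.
Missing concentrations propagate as missing rows and are excluded from HI
sums.

## Monte Carlo

Input uncertainty is declared per parameter as log-normal (log-space mean
and sd), gamma (shape, scale), normal (mean, sd; negative draws rejected
and resampled, with a cap of 1000 × n_iter redraws), or constant.
Concentration laws can be fitted from a survey — log-normal via moments of
the log-values, gamma by method of moments (shape = m²/v, scale = v/m),
normal by sample moments, all with ddof = 1 — or given explicitly.
Default fitted families: log-normal, with gamma for Ni.

The draws are carried through the *deterministic* dose and risk functions:
exposure-profile fields accept numpy arrays, so the probabilistic and
point pipelines share one code path and the all-constant case collapses to
the deterministic result exactly. Sampling order is fixed (sorted
parameter keys), making every summary a pure function of (specs, profiles,
toxicity, n_iter, seed). Defaults: 10,000 iterations; percentiles
5/50/95, estimated by linear interpolation between order statistics
(numpy's default, the type-7 estimator). Inputs are sampled independently;
no correlation structure is supported — a documented limitation, since
e.g. body weight and skin surface area co-vary in reality.

## Spatial interpolation

IDW predicts `Σ wᵢvᵢ / Σ wᵢ` with `wᵢ = dᵢ⁻ᵖ`; a target within 1e-9 of a
sample point returns that sample's value exactly. Distances are haversine
great-circle km by default — at study extents of ~1° the Euclidean-degree
approximation distorts east–west distances by cos(latitude) — with a
Euclidean option for abstract fixtures. Power p = 2 and an all-points
neighbourhood are defaults; both configurable, k-nearest optional. The
computation anchors at the minimum observed value so a constant field is
reproduced exactly (and LOOCV RMSE is exactly 0 there). Predictions are
convex combinations of the data, hence always within the observed range.
Accuracy is leave-one-out RMSE in mg/kg. No kriging or variogram
modelling is attempted.

## Synthetic surveys

The generator emulates the statistical structure of a small industrial-
district survey: `n_sites` (default 21) coordinates uniform over a
bounding box (default 13.0–13.7° N, 74.6–75.0° E, a ~78 × 43 km coastal
strip), per-metal independent log-normal concentrations, and optional
hotspots that multiply all metals at sites within a radius of an
industrial center. The default design's per-metal parameters are set from
reported min–max ranges for such districts (As 0.007–391.8, Cd
0.001–17.45, Cr 0.03–589.2, Cu 0.019–2499.6, Fe 6.6–166447, Ni
0.047–2608, Pb 0.22–2294, Zn 0.033–2625 mg/kg) by placing the central
99.9% interval of the log-normal exactly on the range: μ = midpoint of the
log-endpoints, σ = log-range / (2 × 3.2905). One hotspot (13.08° N,
74.78° E, 6 km radius, ×3) mimics southern industrial clustering. Seasons,
when enabled, are independent concentration redraws at fixed site
locations.

What the generator does *not* emulate: inter-metal correlation (industrial
sources co-emit), spatial autocorrelation beyond the hotspot step,
measurement error, censoring at detection limits. Tests passing on
synthetic surveys therefore demonstrate correctness of the computations
under the declared distributional assumptions, not predictive validity on
any real site.

## Numerical choices and problem sizes

- PLI via log-mean-exp; Igeo errors distinguish "undefined" (c ≤ 0) from
  "invalid" (b ≤ 0).
- CSV round-trips use pandas' round-trip float parser so written tables
  re-read bit-exactly.
- The test suite runs the Monte Carlo oracle checks at 10,000 iterations
  and the end-to-end smoke at 21 sites × 10,000 draws × a ~50 × 29 IDW
  grid; the whole suite completes in well under a minute on one CPU.
- Statistical tests use 3-standard-error bands (moment recovery, with
  delta-method asymptotics for the gamma moment estimators) and a 2%
  relative band on the simulated 95th percentile against the closed-form
  log-normal quantile.

## Known limitations

- Single-medium (soil contact) exposure only: no food-chain, groundwater
  or indoor-dust pathways.
- Linear slope-factor cancer model; no age-dependent adjustment factors.
- Independent-input Monte Carlo (see above).
- IDW is an exact deterministic interpolator; it provides no prediction
  variance. LOOCV RMSE is the only accuracy measure.
- The toxicity registry is a convenience default; values should be
  reviewed against current IRIS/RAIS entries for regulatory use.
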