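# Methods

## Scope and data model

All computations operate on "cubes": (cell × time) arrays wrapped in
`xarray.DataArray`, with integer cell ids, per-cell latitude/longitude and a
calendar time axis. Cells are statistically exchangeable — there is no
spatial autocorrelation in the generator and no area weighting in any
composite — so "spatial" statements are statements across the cell sample.

## The SSEB evapotranspiration model

Daily latent heat flux is the residual of net radiation after the sensible
heat implied by the midday surface–air temperature gradient:

ET = (1 − Cp·ρ·(LSTmax − Tamax)·(A·ga)/(A·Rsmax)) · Rnmean,

Cp = 1005 J kg⁻¹ K⁻¹, ρ = 1.23 kg m⁻³. The diurnal-amplitude multiplier
A = 1.4 is applied to both the aerodynamic conductance and the maximum net
shortwave radiation; written this way it cancels algebraically, and the
implementation keeps it as an explicit parameter purely so sensitivity
checks can confirm the cancellation. Daily minimum surface and air
temperatures are assumed equal, which is why only the maxima appear.
Aerodynamic conductance is cover-weighted: 0.06 (tree), 0.0345
(shrub+grass), 0.002 (bare soil) m s⁻¹, residual cover counting as soil.
Negative ET (strongly heated surface) is clipped at zero and clipping is
logged so it stays auditable; the exact algebraic inverse (used by the
generator to manufacture LST from a prescribed ET) is only defined on
0 ≤ ET ≤ Rnmean with Rnmean > 0.

## Pre-processing conventions

* 16-day moving-window means on an 8-day stride produce the common 8-daily
  grid; a window with more than 20% of its days missing is missing. The
  same ≥80%-valid rule applies to every windowed statistic (daily summaries
  from hourly data, monthly climatologies) for a single consistent
  missing-data policy.
* The calendar month of an 8-daily step is taken from its centre date —
  unbiased for windows straddling month edges.
* Anomalies are computed climatology-first: monthly mean seasonal cycle
  removed, then a LOWESS trend (neighbourhood fraction 0.4, local linear)
  of the deseasonalized residual. The reconstruction identity
  climatology + trend + anomaly = raw holds exactly wherever raw is
  defined. LOWESS runs without robustness iterations: on (near-)noise-free
  series the residual MAD collapses to zero and robust re-weighting
  degenerates, whereas the plain local-linear fit reproduces a line
  exactly. Cells with fewer than 10 valid points fall back to a constant
  (mean) trend.
* With only a few years of record, the monthly climatology absorbs part of
  any secular trend and part of the drought signal itself; anomalies of a
  climatology-plus-trend input are therefore small but not exactly zero
  (a sawtooth at the few-percent level). This is inherent to the
  month-grouped convention, not an implementation artifact.
* 1-m soil moisture is the 0.07/0.21/0.72 thickness-weighted mean of the
  three soil layers. The aridity index divides mean net radiation by
  precipitation converted at λ = 2.5×10⁶ J kg⁻¹ (1 mm day⁻¹ ≈ 28.94 W m⁻²);
  AI > 1 is "dry".
* Analysis masks: vegetation cover ≥ 5%, irrigation fraction ≤ 10%; for
  VOD-ratio analyses only, cells with growing-season midday VOD above the
  midnight mean are also excluded (their night-time refilling assumption is
  violated). Tree vs short-vegetation dominance uses tree/(shrub+grass)
  with threshold 0.5.

## Drought definition

Growing season: air temperature above 5 °C and the month's SIF climatology
above 0.2 mW m⁻² sr⁻¹ nm⁻¹ (both strict). Severe-drought cells are those
whose lowest yearly minimum of 40 years of monthly soil moisture falls in
the study window; rank ties go to the latest year (inclusive reading of the
study window), and cells with fewer than 30 valid years are excluded. The
8-daily peak is the in-season minimum (ties: earliest step); an anomaly
variant takes the minimum of anomalies instead. Durations count consecutive
negative-anomaly steps walking backward (development, including the peak)
and forward (recovery) until the first non-negative step; a missing value
or the record edge censors the count. The display/trajectory window is
[peak − 12, peak + 11] — exactly 24 steps ≈ 3 months either side, with the
peak as the 13th element; the asymmetry is a fixed convention. The severity
variant additionally requires soil moisture at the peak below the 40-year
calendar-month mean minus 1.5 SD (months grouped exactly as in the
climatology).

## Two-model decomposition

Per cell and target stream (SIFrel, ET, VOD ratio), on growing-season
anomalies:

* **Structure-only model**: bagged regression trees with the structure
  proxy (LAI; NIRv via a config switch, no separate code path) as the only
  predictor. Leave-out blocks of 24 steps (192 days; 12 and 6 as
  robustness settings) tile the record from its start, and each block is
  predicted by a model trained with that block excluded — so
  drought-period predictions extrapolate structure–target relationships
  learned outside the drought.
* **Full model**: the same ensemble on structure plus met anomalies
  (Ta, shortwave, VPD, soil moisture, precipitation), trained on the whole
  growing season. This asymmetry (only the structure model is block
  scheduled) is deliberate and matches the asymmetric role of the two
  models; a toggle applies leave-out scheduling to the full model too.
  Out-of-bag R² = 1 − SSE_oob/SST on the training steps screens cells:
  oob ≤ threshold (0 by default; 0.1/0.2 as stricter settings) are
  dropped. Raising the threshold can only remove cells.
* **Physiological component** = full − structural prediction, per step —
  an identity by construction, which the tests assert exactly.

Ensemble settings: 150 trees, minimum leaf 5, unlimited depth, per-cell
seeds derived from the master seed and cell id. The ensemble size is a
bias/variance/runtime compromise: recovery of the planted physiological
signal on the default ensemble is essentially flat beyond ~100 trees,
while OOB-R² estimates are already stable at the ~100–150 growing-season
samples a cell provides.

Variant decompositions: (i) ordinary least squares on the same predictors,
physiology read as the sum of fitted met terms (collinear columns dropped
by pivoted QR); (ii) Shapley contributions of the met predictors in the
full model. Shapley values are interventional — coalition value
v(S) = E_b[f(x_S, b_↽S)] over a background sample — computed by exact
enumeration for ≤10 features and by permutation sampling above, both of
which satisfy base + Σφ = f(x) to machine precision because every
permutation telescopes.

## Attribution and reported statistics

The spatial response is each kept cell's mean physiological anomaly over
the development window [peak−12, peak] (recovery: (peak, peak+11]).
Drivers: aridity, tree cover, development (and for recovery targets also
recovery) duration, and met anomalies averaged over the matching windows.
A bagged-tree model across cells is scored by 5-fold cross-validation R²
(pooled out-of-fold predictions, seeded folds) and drivers are ranked by
mean |Shapley| reported unnormalized, in response units; |Spearman ρ| gives
a collinearity-robust alternative ranking, with top-5 overlap reported.

Composites are unweighted means across cells with ≥20 of 24 valid window
steps; the standard error uses the standard deviation across the
every-third-cell subsample (offset (0,0) by default) divided by √(subsample
size), reducing the effect of spatial autocorrelation in real grids.
Aridity classes are quantiles with near-equal counts. The physio/total
ratio is computed on drought-window *medians* per cell (the per-step
alternative is noisier where the total crosses zero; window medians are the
fixed convention) and then medianed per class, skipping cells with |total|
below machine epsilon. Significance: 1000 draws with replacement from the
cell's same-season pool (±2 eight-daily steps around the peak's calendar
position, non-drought years only); a cell is flagged when the observed
value leaves the 2.5–97.5 percentile range, and a bin gets a dot when more
than 60% of its cells are flagged (strict). Pools under 10 values leave a
cell unflagged.

## The synthetic generator

The generator emulates the *structure* of the observational problem, not
any particular region:

* 40 years of daily meteorology per cell (temperature, net shortwave, net
  radiation, precipitation) from day-of-year sinusoids plus AR(1)
  anomalies; one RNG stream per variable, split from the master seed, so
  adding a stream never perturbs the others. A leap day makes the forcing
  exactly periodic only over the 4-year calendar cycle.
* Soil moisture from a 1-m bucket: precipitation in, demand-proportional
  outflow (potential rate = the latent-heat equivalent of net radiation),
  fast drainage above field capacity (0.35), bounds [0.02, porosity 0.45].
  Cell aridity targets in [0.5, 2.0] set the mean precipitation.
* Precipitation is summer-dry (minimum ~early June, amplitude 35%), so the
  climatological rains are already recovering when the imposed suppression
  ends — the suppression window, not the seasonal cycle, controls the
  timing of the soil-moisture minimum.
* The drought: precipitation multiplied by 0.05 for 15 eight-day steps
  (120 days) starting day-of-year 121 of the designated drought year in
  the configured drought cells (default: half the ensemble). This reliably
  produces the 40-year monthly minimum in those cells, with the 8-daily
  peak inside the suppression window.
* Structure: LAI tracks a 64-day trailing mean of soil moisture lagged by
  2 steps (16 days), times a seasonal shape, with at most a 30% leaf-area
  loss at full depletion — months of drought dent LAI by ~10% while φ
  halves, the lagged-structure / fast-physiology regime the decomposition
  assumes. Light interception f = 1 − exp(−0.5·LAI) carries structure into
  every stream.
* Physiology: φ = min(1, (SM/SM_crit)^a) · exp(−b·max(0, VPD − VPD_clim)),
  raised to a per-cell severity exponent that increases with aridity and
  decreases with tree cover — the planted spatial drivers the attribution
  stage must find. SM_crit is 0.85 of the cell's own non-drought
  5th-percentile soil moisture, so φ = 1 under climatological moisture and
  VPD, and drought-cell φ minima land near 0.5 at the defaults
  (a = 1, b = 0.4 kPa⁻¹). No functional form for this downregulation is
  observationally established; this one is a modelling choice, chosen for
  smoothness, boundedness in (0, 1] and sensitivity to both soil drought
  and atmospheric demand.
* Imprinting: SIF = c·f·φ (+noise) with NIR radiance varying only with
  structure, so SIFrel = SIF/NIR carries φ multiplicatively; ET = 0.5·Rn·f·φ
  with midday LST manufactured by the exact SSEB inverse (ET round-trips
  through the forward model to 1e-9 before noise); VOD_night tracks a
  biomass proxy and VOD_day = VOD_night·(1 − δ(1−φ)) with δ = 0.3, so the
  day/night ratio encodes φ and its structural part is constant. In this
  generator the drought VOD-ratio anomaly is therefore *negative* — a sign
  convention of the imprinting, carrying no claim about real canopies.
  Observation noise is Gaussian per stream at a configured fraction
  (default 10%) of each cell's own temporal signal SD — per-cell scaling,
  so structurally offset cells do not set other cells' noise floors; LST
  noise scales with each cell's SD of the surface–air gradient.
* The truth dataset stores φ, soil moisture, noiseless LAI, each stream's
  structural part and physiological imprint (struct·(φ−1), and −δ(1−φ) for
  the ratio), and true ET; with zero noise the stated compositions
  reproduce every stream exactly, and everything is bit-reproducible from
  the seed.

**What passing tests show, and what they do not.** The generator has no
spatial autocorrelation, no orbital/angular sampling, no clouds, no
retrieval biases, and its physiological truth is a single smooth scalar
factor. Recovery of φ here demonstrates that the decomposition machinery
is consistent — that it finds a multiplicative physiological signal hidden
under structure and noise when one exists, and reports ~zero when none
does — not that real SIF/ET/VOD physiology is captured with the same
fidelity.

## Problem sizes and numerical choices

The default validation ensemble is 200 cells × 5 study years (100 drought
cells), chosen to give stable pooled statistics while a full three-stream
decomposition plus the null control completes in minutes on one CPU; unit
tests use 40-cell ensembles. Ties in minima break to the earliest step
(peaks) or latest year (yearly ranking), as stated above. Bootstrap and
Shapley computations are seeded and bit-reproducible. Degenerate inputs —
zero seasonal SD (severity), empty null pools, constant drivers
(Spearman), rank-deficient OLS designs — return the documented fallbacks
rather than raising.

## Known limitations

* ET physiology cannot be separated from direct meteorological effects on
  atmospheric demand; the decomposition attributes both to the met-driven
  component.
* The month-grouped climatology over a short record aliases part of the
  drought into the seasonal cycle, shrinking anomaly magnitudes.
* The structure proxy is assumed to capture all structural variance at the
  8-daily scale; physiological changes that co-vary with LAI within a step
  are counted as structural.
* Leave-out blocks tile from the record start; the block containing the
  peak defines the excluded drought window, so block alignment relative to
  the drought is a convention, not estimated.
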