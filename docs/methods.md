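# Methods

This note records the model, its parameters, the synthetic data the tests
run on, and the numerical and design choices made where the design was
genuinely open.

## Climate envelope and habitat suitability

The envelope for a species is the sample mean m and covariance S of the
climate quadruplets C = (T*_am, P*_am, P*_min, N*) extracted at its
occurrence sites and ages. Suitability is

    H(C) = 1 − χ²_CDF(ζ²; d),    ζ² = (C − m)ᵀ S⁻¹ (C − m),

with d equal to the number of climate variables (4 by default; the
implementation supports any d, tested at d = 2, where H = e^(−ζ²/2)).
H is 1 at the envelope centre, strictly decreasing in ζ², and — if the
occurrence climates were truly multivariate normal — the probability that
a random draw from the niche lies further from the centre than C does.

Choices:

* **Covariance divisor.** The unbiased estimator (N − 1). Nothing in the
  source formulation pins the divisor; the in-sample identity
  mean(ζ²) = d(N − 1)/N, which the tests assert exactly, documents the
  choice and would flip to mean(ζ²) = d under the biased divisor.
* **Extraction.** Nearest land grid cell (great-circle distance) and
  nearest 1,000-year slice — no interpolation — matching the idea of
  subsampling the simulated fields at the data sites. Ocean-located
  records snap to the nearest land cell with the snap distance logged.
* **Age uncertainty.** Each record contributes `n_draws` rows (default
  10) with ages drawn uniformly on [t − Δt, t + Δt]. Uniform is the
  assumption-minimal reading of a half-width uncertainty; a truncated
  normal with sd = Δt/2 is available by option. Equal row weights mean a
  layer dated k times carries k× weight in the multiple-date scenarios —
  a deliberate property of those scenarios, removed by the single-date
  modes.
* **Degenerate covariance.** If cond(S) > 10¹⁰ a diagonal ridge
  ε·diag(S) with ε = 10⁻⁸ is added and logged (zero-variance diagonal
  entries are floored at the mean positive variance so the ridge always
  regularises); passing `ridge=None` makes this a hard error. Fewer than
  5 usable records is always an error.

## Downscaling

Bilinear interpolation to the fine grid (the conventional minimal choice;
values at coarse nodes are preserved exactly), then per-month corrections:
T* = T − gΔh with g = 0.006 °C m⁻¹, and the Clausius–Clapeyron factor
exp[aT*/(T* + b) − aT/(T + b)] with a = 17.625, b = 243.04 °C applied to
monthly precipitation. Annual aggregates: T_am = mean, P_am = sum
(mm yr⁻¹), P_min = min of the *corrected* monthly precipitation. Whether
the minimum should be taken before or after correction is not prescribed
anywhere; correcting first is the physically coherent order (the minimum
of what actually falls at the downscaled temperature) and is what the
implementation does. Δh is treated as time-constant: no time-varying fine
topography exists, so the static difference field is used throughout.
Fine points outside the coarse hull are nearest-neighbour extrapolated
with a warning. A trajectory already expressed as annual envelope
variables can bypass the monthly path (`downscale_annual`); both paths
share the same correction kernels.

## NPP diagnostic

Tree fraction τ = 0.95{1 − e^[−β(T* − T_m)]}·p*^α/(p*^α + f) with
f = b·e^[γ(T* − T_m)], β = 0.45 °C⁻¹, α = 3, b = 2.6×10⁶, γ = 0.155 °C⁻¹,
T_m = −15 °C, capped to [0, 1] (below T_m the leading factor is negative
and the cap yields 0; at p* = 0 the ratio is taken as its limit 0). NPP:

    N* = {6116[1 − e^(−0.0000605 p*)](1 − τ) + τ·min(FP, FT)}·f(CO₂)
    FP = 0.551·p*^1.055/e^(0.000306 p*),  FT = 2540/[1 + e^(1.584 − 0.0622 T*)]
    f(CO₂) = 1 + 0.4·ln(CO₂/280)/ln 2.

The precipitation constants presuppose mm yr⁻¹; `npp_field` refuses
fields whose units attribute disagrees. min(FP, FT) is evaluated per
cell. N* is evaluated from annual means of the downscaled fields,
consistent with the annual units of every constant. f(CO₂) stays positive
for CO₂ > 280·2^−2.5 ≈ 49.5 ppm, far below any plausible input.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the envelope model
consumes, not climate physics:

* per-cell series = spatial mean map (base + meridional gradient + smooth
  seeded bumps) + spatially uniform Milankovitch sinusoids (defaults from
  the 21/41/100/405-ka set, glacial–interglacial amplitudes: ~2 °C in
  temperature, ~10 % of mean in the moisture variables) + AR(1) noise
  (lag-1 coefficient 0.7 per 1-ka step) whose innovations are coupled
  across the four variables by the Cholesky factor of a positive-definite
  4×4 correlation matrix — matching the co-varying components the
  envelope assumes. Precipitation and NPP are clipped at 0.
* The study-scale default is 2,000 slices of 1,000 years (2 Myr); tests
  run 200–500 slices on grids of tens of cells so the whole suite
  finishes in seconds.
* Fossil records are drawn by proposing uniform land cells and uniform
  ages, accepting with probability equal to the suitability the *true*
  envelope assigns to the local climate — the same 1 − χ²_CDF transform
  the analysis uses, so parameter-recovery tests are self-consistent.
  Unreachable centroids fail after a bounded number of proposals with a
  diagnostic.

Not emulated: spatial autocorrelation calibrated to any real simulation
(smoothness is a free parameter), ice-sheet or CO₂ forcing physics,
teleconnections, land-mask realism, or taphonomic/sampling bias in the
fossil record. Passing tests therefore demonstrate correctness of the
statistical machinery under known structure, not realism of any
particular palaeoclimate reconstruction.

## Scenario resolution of the species database

Ages outside [30, 2000] ka are dropped; Australia and the Americas are
excluded by the region column when present, otherwise by bounding boxes
(Americas lon ∈ [−170, −30]; Australia lon ∈ [110, 155] ∧ lat ∈ [−45,
−10]); *H. habilis* and *H. ergaster* merge into one early-African-*Homo*
group. Tier 1 keeps only single-attribution (core) entries; tier 2
resolves multi-attribution entries by a seeded uniform choice (a missing
seed is a hard error — reproducibility contract). Single-date modes
collapse each archaeological layer to one entry whose age envelope is
[min(t − Δt), max(t + Δt)] (midpoint age, half-span uncertainty). Layers
are keyed by (site, layer, resolved species): if a layer contains
confidently attributed entries of two species, each species keeps one
entry — no source defines the rule for that corner case, and dropping
either record would silently discard confident data. Entries with an
empty layer id form their own layer.

## Scrambled-trajectory null model

`scramble_fields` applies one random permutation of the time indices per
grid cell, jointly to all four variables, which preserves each cell's
time-mean state and 4×4 cross-variable covariance *exactly* (permutation
invariance; the acceptance run measures the residual at ~10⁻¹⁵ relative).
A global single-permutation mode is provided for users who need the
null's spatial coherence preserved; per-cell is the default reading of
"randomising the time variability of the climate vector". The null
envelope is refitted on the scrambled trajectory restricted to the
species' overall fossil age window [min(t − Δt), max(t + Δt)], so the
null only redistributes climate states the species could have met. One
seeded scramble is used per run (an ensemble can be formed by looping
over seeds); `diff_test` then runs a per-cell paired t-test of H(t)
against H_scr(t) over time slices — pairing by time slice at a fixed cell
is the only pairing consistent with testing the time-averaged difference
at each grid point. Zero-variance cells get p = 1 when the mean
difference is 0 and p = 0 otherwise, both logged. No multiple-testing
correction by default (raw p < 0.05 with the |ΔH| > 0.05 effect-size
floor); Benjamini–Hochberg is available as an option.

**Calibration caveat.** The paired t-test is exactly calibrated when the
per-cell difference series has independent, zero-mean increments — the
construction used in the calibration tests (independent Gaussian
suitability fields at 200 cells × 50 replicates; measured type-I rate
0.050 ± 0.002 at α = 0.05). The *full* pipeline run on fossils placed
independently of time is not exactly calibrated by construction: with the
same envelope on both sides, per-cell time-means of H and H_scr are
identical (scrambling is a permutation), so any rejection is driven
entirely by the sampling noise of refitting the envelope, which shifts
the whole difference field by a per-replicate offset the t-test cannot
distinguish from a trajectory effect. The package therefore reports the
full-pipeline significant fraction as a descriptive quantity and reserves
the binomial calibration claim for the construction that satisfies the
test's assumptions. Relatedly, the scrambled-null envelope is *broader*
than the real one (it mixes climate states across times), so its absolute
suitability at occupied cells can exceed the real model's; what the real
trajectory demonstrably buys is temporal discrimination — the excess of
suitability at the actual occurrence times over the cell's time-mean —
which is consistently larger for the real model on forcing-dominated
synthetic data (measured ~0.45–0.51 vs ~0.34–0.40 across seeds).

## Numerical details

* Time axes are ages in ka before present, oldest first; nearest-slice
  lookup is done by explicit |Δage| minimisation so axis orientation
  never matters.
* Great-circle distances use the haversine formula with mean Earth radius
  6,371 km (the metric's radius is conventionally unstated).
* Degree-box membership (regional averages, site vicinities) takes cell
  centres in [centre ± width/2], half-open on the east/north edges, so
  adjacent boxes tile without double counting.
* The "species overlap" appears in two forms on purpose: the pointwise
  product of suitabilities (used for zonal-mean Hovmoeller diagrams,
  computed per slice before zonal averaging) and the per-cell temporal
  covariance (used for maps); both usages occur in the literature this
  design follows, and they answer different questions.
* Presence-probability curves use the same uniform age kernel as the
  Monte-Carlo age sampling, superposed and normalised to peak 1.
* NetCDF I/O uses xarray's scipy backend (classic NetCDF-3), with
  CF-style units attributes (degC, mm/year, mm/month, gC/m2/year, ppm);
  boolean masks are stored as bytes.

## Problem sizes

The test-suite and acceptance runs use grids of 48–400 cells and 60–500
time slices, and 150–500 synthetic fossil records — sizes chosen so the
statistical assertions (autocorrelation recovery, binomial calibration
bands, 3·sd/√n centroid recovery) have the power stated in each test
while the whole suite completes in well under a minute.

## Known limitations

* The envelope is a single Gaussian-like ellipsoid: multimodal niches,
  dispersal limits, biotic interactions and sampling bias are out of
  scope by design.
* Monte-Carlo rows from the same record are treated as independent in
  the covariance, which slightly understates envelope uncertainty when
  Δt is large relative to the climate decorrelation time.
* Synthetic mean maps and forcings are spatially simple; conclusions
  about spatial pattern realism cannot be drawn from them.
* The single-date layer combination assumes the layer's extreme age
  bounds define a uniform envelope, which can be wider than a proper
  hierarchical age model would give.
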