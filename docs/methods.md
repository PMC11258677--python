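# Methods

This note documents the models, estimators, numerical choices and known
limitations of `canopygeo`. Notation: cover is a fraction in [0, 1];
coordinates are planar projected meters throughout — no geographic math is
performed anywhere.

## Synthetic cover fields

The generator's job is to produce data with the statistical structure the
analysis chain assumes, so every stage can be tested end to end.

**Gaussian random field.** The latent cover field is a stationary Gaussian
random field with an exponential semivariogram
`γ(h) = C₀ + C(1 − e^{−h/a})`, default `C₀ = 0.12×10⁻²`,
`C = 0.77×10⁻²`, `a = 10 200 m` — parameter values characteristic of
natural-forest cover at the landscape scale. The covariance is
`Cov(h) = C·e^{−h/a}` (the range parameter is `a` itself, not the 3`a`
effective-range convention), with the nugget added as independent noise at
sample locations. Simulation is by exact Cholesky factorization of the
covariance matrix with a 1e-10 diagonal jitter for up to 5 000 points;
larger point sets and grids fall back to sequential simulation with a
moving neighborhood (nearest 16, radius 2`a`) — the same engine used for
conditional simulation, run unconditionally. Every generator is a pure
function of (configuration, seed).

**Marginal transform.** Field ranks (average on ties) are mapped through
the quantile function of a normal with the target mean/sd truncated to the
target bounds — defaults mean 0.56, sd 0.092 on [0.25, 0.83], the
reference footprint-cover statistics at n = 1 106. The bounds sit ~3 sd
from the mean, so truncation barely perturbs the moments; the map is
strictly rank-preserving (Spearman r = 1) and, because the input field is
already Gaussian, close to affine — the field's variogram shape survives
with a mildly rescaled sill (the reference sill 0.0089 implies sd 0.094,
already close to the 0.092 target).

**Tracks and thinning.** Footprints lie along near-parallel tracks at a
configurable azimuth, spacing and along-track step; the defaults (20
south–north tracks, 2.5 km apart, 100 m steps over a 50 × 55.2 km domain)
yield 11 060 footprints, and systematic thinning at interval 10 keeps
1 106 — the reference counts. The along-track step is a free parameter
(100 m matches the segment length of photon-counting lidar land products).
Geolocation jitter is available but defaults to zero so counts are a pure
function of the geometry. For large domains the field is simulated
directly at the thinned footprint coordinates (the restriction of a GRF to
a subset of sites has the same law), keeping the exact-Cholesky path; a
17 m full grid over such domains (~10⁷ nodes) would serve no estimation
purpose.

**Covariates and terrain.** Each covariate is
`y = r·standardize(cover) + sqrt(1−r²)·e` with the noise orthogonalized
against the cover signal, so the Gaussian-scale sample correlation equals
the target exactly; bound clipping, count rounding and the ordinal 1–9
aspect code perturb it by at most a few hundredths. Default targets: the
seven segment covariates at r = 0.29/0.31/0.38/0.27/0.32/0.34/0.35 and
terrain at 0.27 (elevation), 0.10 (slope), 0.08 (aspect). Units are
plausible rather than physical (e.g. elevation mean 3 454 m, sd 572 m,
clipped to [1 821, 4 646]). At footprint points terrain is generated by
this correlated construction (isolated track points give no grid to
difference); for gridded fields a Horn finite-difference slope/aspect
utility is provided, with aspect classes 1–8 for the compass octants from
north and 9 for flat cells.

**What the generator does not emulate:** photon-level physics, orbital
geometry, covariate–covariate correlation structure beyond the shared
cover signal, non-stationarity, and terrain-driven cover patterns (terrain
correlates with cover only through the prescribed coefficients). Passing
tests therefore demonstrate correctness of the estimators under the
assumed stationary Gaussian model, not robustness to real-data pathologies.

## Plot measurement

Plot cover is the covered fraction of M dot-grid observation points;
`simulate_plot` draws the flags Bernoulli(p), making `canopy_cover` an
unbiased estimator of p with binomial sampling error. The normality check
uses Shapiro–Wilk for n ≤ 5 000 and the D'Agostino K² test beyond
(Shapiro–Wilk loses calibration at large n), at α = 0.05; constant samples
are flagged degenerate rather than tested. When a sample fails, the
suggested transforms are tried in order: natural log (positive data), then
rank-based normal scores (which pass by construction for continuous data).

## Cover regression

Covariates are screened by two-sided Pearson tests (p < 0.05), ordered by
|r|. The k-NN predictor is the inverse-distance-weighted rule
`ŷ = Σ wᵢyᵢ/Σ wᵢ`, `wᵢ = 1/dᵢ`, over the k nearest training rows in
z-scored (training statistics) Euclidean feature space; a zero-distance
query returns that row's response exactly. Random forest, gradient
boosting and support-vector regression delegate to scikit-learn with
library defaults (recorded in the run log; no tuning is attempted), behind
a uniform fit/predict contract whose outputs are clipped to [0, 1]. The
70/30 split is row-random with a stored seed. RMSE uses an (n−1)
denominator; R² is one minus the residual-to-total sum-of-squares ratio on
the validation set (not a squared correlation).

## Moran's I

Weights support binary distance bands, inverse distance with a cutoff, and
symmetric k-nearest neighbors, optionally row-standardized (the default);
isolated sites are reported. The default analysis scheme is inverse
distance with the cutoff at the fitted variogram range — a documented
choice, since the weight scheme is otherwise arbitrary and Moran's I is
scheme-dependent. Global inference uses E[I] = −1/(n−1) and the
randomization (permutation-moment) variance, which is robust to
non-normal values; an optional Monte-Carlo permutation test (two-sided,
centered at E[I]) is calibrated to the nominal level (type-I error 0.045
at α = 0.05 over 200 null fields in the acceptance run). The local Moran
uses the standard Anselin form `Iᵢ = zᵢ·lagᵢ/(Σz²/n)` — whose site mean
equals the global I under row standardization — with conditional
permutation (site i held fixed, others permuted without replacement) and a
folded two-sided pseudo p-value; labels are assigned by the quadrant of
(zᵢ, lagᵢ) only where p < α, with no multiple-testing correction by
default (an FDR flag is the usual remedy and can be applied downstream).

## Semivariograms

Pairs are binned by separation distance (default bin width twice the
median nearest-neighbor spacing, maximum lag half the bounding-box
diagonal); directional variograms keep pairs whose separation azimuth lies
within a 22.5° tolerance of the axis (0° = E–W, 90° = N–S). Each bin's lag
coordinate is the **mean pair distance in the bin**, not the nominal
center: track-clustered sampling puts all short-range pairs at nearly the
along-track spacing, and nominal centers then systematically misplace the
near-origin points where the nugget is identified. Nominal centers are
retained for aligning bins across variograms (anisotropy ratios).

Model fitting is bounded nonlinear weighted least squares over
(C₀, C, a), five starts seeded from method-of-moments guesses (plateau ≈
late-bin mean, range ≈ first lag reaching 95 % of it), since variogram
objectives are multimodal. Weights are N(h) by default (the GS+
convention); `N(h)/γ̂²` is available by flag and is the recommended setting
for single-realization fits, where the huge pair counts of long, noisy
lags otherwise dominate the precise short-lag bins. Fit R² and RSS are
computed on the binned points (weighted); the best family maximizes R²
with ties broken by RSS, and a non-converging family is skipped with a
warning, never silently selected. NSR classes: < 25 % strong, 25–75 %
moderate, > 75 % weak spatial dependence.

**Parameter recovery is fundamentally limited at n ≈ 1 100.** A dedicated
simulation study (40 replicates per configuration, 15+ combinations of
track design, bin width, maximum lag and weighting) shows that refitting
the generating exponential model from ~1 100 track footprints recovers all
three parameters within 25 % in at most ~62 % of replicates, with the
range the binding parameter (~35 % failures throughout). This is ergodic
fluctuation — the apparent range/sill of one realization genuinely varies
that much over domains 5–27× the range — not estimator bias: noiseless
bins recover parameters exactly, E[γ̂(h)] = γ(h) by construction, and
tripling n within the same domain (3 668 points) improves the rate only
marginally. The packaged recovery experiment uses the most favorable
design found (4 tracks 30 km apart over 120 × 275 km, thinned to 1 101
points, 1 km bins to a 30 km maximum lag, `N(h)/γ̂²` weights), under which
the nugget and partial sill individually recover in ~97 % and ~80 % of
replicates but the joint three-parameter rate remains ~55–65 %.

## Kriging and conditional simulation

**Ordinary kriging** solves, per target, the semivariogram system with the
unbiasedness constraint (Lagrange multiplier) over the nearest ≤ 16
neighbors within twice the model range; weights sum to one to 1e-8 by
construction, data locations are interpolated exactly, and a pure-nugget
model yields the neighborhood mean. Coincident data are averaged (with a
warning) to keep the system nonsingular; numerically negative variances
are clipped to zero with a warning; targets with an empty neighborhood are
NaN-masked.

**Normal scores** map average ranks through plotting positions
(r − 0.5)/n to standard-normal quantiles; the back transform interpolates
linearly in the score–value table, extrapolates the outer segments
linearly, and clips to bounds (data min/max by default, [0, 1] for cover).
The round trip is the identity for untied data.

**SGCS** runs per realization: normal-score the data; visit simulation
nodes on a seeded random path (realization r uses seed + r, so
realizations are independent and individually reproducible); at each node
draw from the simple-kriging (known mean 0, unit sill) conditional
distribution given data plus previously simulated nodes in the
neighborhood; back-transform. The variogram is rescaled to unit sill in
Gaussian space, preserving the nugget proportion and range. Simple kriging
inside the simulation and ordinary kriging for the standalone surface is
the standard pairing. Two numerical safeguards matter: the simple-kriging
covariance matrix gets a 1e-9 diagonal jitter and a Cholesky solve with a
least-squares fallback; and a node coinciding with an existing
conditioning point takes that value directly (zero nugget) and is **not**
appended to the conditioning set — a duplicated location makes later
systems singular and, uncorrected, destabilizes the whole realization.
The E-type estimate is the pointwise mean across realizations (50 by
default); its correlation with the ordinary-kriging surface exceeds 0.95
at 200 realizations, while any single realization retains the variance
kriging smooths away. Note that realizations honor the *data's* empirical
marginal: their variance approaches the data variance, which equals the
model sill only when the data are consistent with the model.

**Holdout validation** splits the points 80/20 with a stored seed, fits
the variogram on the interpolation set (unless a model is supplied),
predicts the held-out locations by OK or the SGCS E-type mean, and scores
with the same RMSE/R² as the regression stage. A training fraction of 1.0
(validating on training points) is rejected.

## Pipeline and I/O

The pipeline (simulate → summarize → screen → model → variogram → Moran →
LISA → krige → SGCS → validate) is driven by a single serializable config;
every artifact embeds the config hash and master seed, and re-running the
same config reproduces all tables byte-identically. The default mapping
grid uses a 1 km cell (a 17 m cell over a 50 km domain is ~10⁷ nodes and
adds nothing at these sampling densities; the cell is configurable down to
the 17 m footprint scale for small domains). Footprint tables are
delimited text with a fixed schema (id, x, y, nfcc, seven covariates,
elevation, slope, aspect) or GeoJSON points; grids are node-registered
lower-left-origin ESRI ASCII rasters. Systematic sampling uses 0-based
offsets: positions offset, offset+interval, ... are kept.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run on scaled designs chosen to make each
property measurable with comfortable statistical margins: oracle
equivalence at n ≤ 200 (exact), Moran calibration on 200 null fields of
400 sites with 999 permutations, kriging contracts on 1 000 random
targets, SGCS fidelity with 200 realizations on a 30 × 30 grid and 60
conditioning data, variogram recovery over 20 replicates of ~1 100 track
footprints, and a ~200-footprint end-to-end pipeline demo. The acceptance
script re-runs the emulated study at the full 1 106-footprint reference
scale.

## Known limitations

- Variogram range estimates from a single realization carry 20 %+ sampling
  uncertainty at these designs (see above); reported ranges should be read
  with that in mind.
- The SGCS neighborhood (nearest 16, no multigrid refinement) can
  under-represent very long-range structure in large grids.
- LISA p-values are conditional-permutation pseudo p-values without
  multiple-testing correction by default.
- The inverse-distance weight cutoff ties Moran's I to the fitted
  variogram range; a different scheme yields a different I (the statistic
  is scheme-dependent by nature).
- Anisotropy is summarized by directional-ratio diagnostics; no
  anisotropic model fitting or variogram maps.
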