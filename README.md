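# canopygeo

Geostatistical analysis of natural-forest canopy cover sampled along
spaceborne-LiDAR footprint tracks.

Photon-counting satellite lidar (ICESat-2/ATLAS-style) observes forests as
dense strips of ~17 m footprints along near-parallel ground tracks. Each
footprint yields segment covariates (canopy photon rate, relative heights,
surface reflectance, ...) from which canopy cover — the fraction of ground
under vertical canopy projection — can be predicted, turning a sparse field
campaign into thousands of spatially referenced cover observations. This
package implements the full downstream analysis of such footprint cover
data, plus a synthetic-data generator so the entire chain is testable
without any satellite download:

1. **plot measurement** — dot-grid plot cover `Cc = m/M`, descriptive
   statistics and the pre-kriging normality check;
2. **modeling** — Pearson screening of covariates, cover regression with a
   native inverse-distance-weighted k-NN plus random forest, gradient
   boosting and support-vector regression, scored by
   `RMSE = sqrt(Σ(yᵢ−ŷᵢ)²/(n−1))` and `R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²`
   on a 70/30 split;
3. **autocorrelation** — global Moran's `I = (n/S₀)·Σ w_pq z_p z_q / Σ z_p²`
   with randomization Z-scores and permutation tests, and the local Moran
   `Iᵢ = zᵢ·Σⱼ wᵢⱼ zⱼ / (Σ z²/n)` with conditional-permutation inference
   and HH/LL/HL/LH cluster labels;
4. **spatial heterogeneity** — empirical (omnidirectional and directional)
   semivariograms `γ̂(h) = (1/2N(h))·Σ (zᵢ−zⱼ)²`, weighted least-squares
   fits of linear/spherical/exponential/Gaussian models
   (e.g. `γ(h) = C₀ + C(1−e^{−h/a})`), the nugget-to-sill ratio
   `NSR = C₀/(C₀+C)` with the conventional <25 % / 25–75 % / >75 % spatial
   dependence bands, and the anisotropy ratio `K(h) = γ̂_θ₁(h)/γ̂_θ₂(h)`;
5. **interpolation** — ordinary kriging `Z*(x₀) = Σ λᵢ Z(xᵢ)` with the
   Lagrange-multiplier system (exact, smoothing), and sequential Gaussian
   conditional simulation (normal scores → random path → simple kriging on
   data + previously simulated nodes → conditional draws), with E-type
   summaries and 80/20 holdout validation.

The synthetic generator produces a Gaussian random field with an
exponential variogram (`C₀ = 0.12×10⁻²`, `C = 0.77×10⁻²`, `a = 10 200 m`),
rank-transforms it to cover units (mean 0.56, sd 0.092 on [0.25, 0.83]),
samples it along 20 tracks to 11 060 footprints thinned systematically
(interval 10) to 1 106, and attaches seven covariates plus terrain with
prescribed Pearson correlations (0.27–0.38 to cover).

## Worked example

```python
import numpy as np
from canopygeo import (build_weights, empirical_variogram, fit_model,
                       global_moran)
from canopygeo.synthetic import make_footprint_dataset

frame = make_footprint_dataset(seed=1)
pts = frame[["x", "y"]].to_numpy()
nfcc = frame["nfcc"].to_numpy()
print(f"footprints: {len(frame)}, cover mean {nfcc.mean():.3f}, "
      f"sd {nfcc.std(ddof=1):.3f}")

emp = empirical_variogram(pts, nfcc)
best, _ = fit_model(emp, families=["exponential"],
                    weight_mode="counts_over_gamma2")
m = best.model
print(f"exponential fit: C0={m.nugget:.5f}, C={m.partial_sill:.5f}, "
      f"a={m.range_:.0f} m, NSR={100*m.nsr:.1f}%, R2={best.r2:.2f}")

w = build_weights(pts, scheme="idw_band", param=m.range_)
res = global_moran(nfcc, w)
print(f"Moran's I = {res.I:.3f} (E[I] = {res.expected:.4f}, "
      f"z = {res.z:.1f}, p = {res.p:.2g})")
```

prints

```
footprints: 1106, cover mean 0.560, sd 0.091
exponential fit: C0=0.00013, C=0.00833, a=5205 m, NSR=1.5%, R2=0.96
Moran's I = 0.574 (E[I] = -0.0009, z = 64.9, p = 0)
```

The 1 106 thinned footprints reproduce the configured cover marginal; the
fitted exponential model describes the binned semivariances well
(R² = 0.96) and the strongly positive Moran's I (0.574 against an
expectation of ≈ 0) confirms spatial agglomeration of cover. Note the
fitted range (5.2 km) underestimates the generating 10.2 km: a single
realization over a domain only ~5 ranges wide carries limited information
about the range parameter (see `docs/methods.md` for the quantitative
analysis of this fluctuation).

A command-line interface mirrors the stages
(`canopygeo simulate|thin|model|moran|lisa|variogram|krige|sgcs|validate|run`);
`canopygeo run --seed 7 --outdir out/` executes the full pipeline and
writes footprint tables, model-comparison tables, Moran/LISA results,
fitted variograms (JSON), kriging/SGCS surfaces (ESRI ASCII grids) and a
reproducibility report embedding the config hash and master seed.

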