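"""Empirical and model semivariograms, WLS fitting, anisotropy.

The semivariogram gamma(h) = E[(Z(x) - Z(x+h))^2] / 2 summarizes spatial
heterogeneity of a regionalized variable such as canopy cover.  Four
classical model families are supported (linear, spherical, exponential,
gaussian), parameterized by nugget C0, partial sill C and range parameter a,
with the exponential written as C0 + C*(1 - exp(-h/a)) (no effective-range
rescaling).  The nugget-to-sill ratio NSR = C0/(C0+C) is classified with
the conventional Cambardella bands: < 25 % strong, 25-75 % moderate,
> 75 % weak spatial autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

FAMILIES = ("linear", "spherical", "exponential", "gaussian")

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "FitResult",
    "empirical_variogram",
    "model_gamma",
    "fit_model",
    "directional_suite",
    "anisotropy_ratio",
    "classify_nsr",
    "FAMILIES",
]


@dataclass(frozen=True)
class VariogramModel:
    """A fitted or assumed semivariogram model.

    Parameters
    ----------
    family : one of ``linear``, ``spherical``, ``exponential``, ``gaussian``.
    nugget : C0 >= 0, the discontinuity at the origin (micro-scale variance
        plus measurement error).
    partial_sill : C >= 0, the spatially structured variance.
    range_ : a > 0, the distance parameter in meters.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.partial_sill < 0:
            raise ValueError("partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        """Total sill C0 + C."""
        return self.nugget + self.partial_sill

    @property
    def nsr(self) -> float:
        """Nugget-to-sill ratio C0/(C0+C) in [0, 1]."""
        if self.sill == 0:
            return 0.0
        return self.nugget / self.sill

    def gamma(self, h):
        """Model semivariance at lag(s) ``h``; gamma(0) = 0 exactly."""
        return model_gamma(self, h)

    def covariance(self, h):
        """Stationary covariance C(h) = C*corr(h), nugget only at h = 0.

        Only defined for bounded families (not ``linear`` beyond the sill
        plateau, which this parameterization caps, so all four work).
        """
        h = np.asarray(h, dtype=float)
        struct = self.partial_sill - (model_gamma(self, h) - np.where(h > 0, self.nugget, 0.0))
        return np.where(h == 0, self.nugget + self.partial_sill, struct)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned empirical semivariances.

    ``lags`` are the mean pair distances per bin in meters (strictly
    increasing), ``gamma`` the semivariance estimates, ``counts`` the pair
    counts N(h) per bin.  ``bin_centers`` are the nominal bin midpoints,
    used to align bins across variograms (e.g. directional ratios); they
    default to ``lags``.  ``direction`` is the compass-style axis in
    degrees (0 = E-W, 90 = N-S) or None for omnidirectional.
    """

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    direction: float | None = None
    tolerance: float | None = None
    max_lag: float | None = None
    bin_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if self.bin_centers is None:
            object.__setattr__(self, "bin_centers", self.lags)
        else:
            object.__setattr__(self, "bin_centers",
                               np.asarray(self.bin_centers, dtype=float))
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.gamma < 0):
            raise ValueError("semivariances must be >= 0")
        if np.any(self.counts < 1):
            raise ValueError("reported bins must have N(h) >= 1")

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class FitResult:
    """One family's weighted-least-squares fit to an empirical variogram."""

    model: VariogramModel
    r2: float
    rss: float
    converged: bool = True


def model_gamma(model: VariogramModel, h) -> np.ndarray | float:
    """Evaluate a variogram model at lag distance(s) ``h`` >= 0.

    gamma(0) = 0 by definition; the nugget appears as the limit from the
    right.  Families:

    - linear:      C0 + C * min(h/a, 1)        (rises to the sill at a)
    - spherical:   C0 + C * (1.5 h/a - 0.5 (h/a)^3) for h <= a, else C0 + C
    - exponential: C0 + C * (1 - exp(-h/a))
    - gaussian:    C0 + C * (1 - exp(-(h/a)^2))
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("lag distance must be >= 0")
    r = h_arr / model.range_
    c0, c = model.nugget, model.partial_sill
    if model.family == "linear":
        g = c0 + c * np.minimum(r, 1.0)
    elif model.family == "spherical":
        g = np.where(r <= 1.0, c0 + c * (1.5 * r - 0.5 * r**3), c0 + c)
    elif model.family == "exponential":
        g = c0 + c * (1.0 - np.exp(-r))
    elif model.family == "gaussian":
        g = c0 + c * (1.0 - np.exp(-(r**2)))
    else:  # pragma: no cover - guarded by VariogramModel
        raise ValueError(model.family)
    g = np.where(h_arr == 0.0, 0.0, g)
    if np.isscalar(h) or np.ndim(h) == 0:
        return float(g)
    return g


def _pair_arrays(points: np.ndarray, values: np.ndarray):
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if points.shape[0] != values.size:
        raise ValueError("points and values length mismatch")
    if points.shape[0] < 2:
        raise ValueError("at least 2 points required")
    d = pdist(points)
    i, j = np.triu_indices(points.shape[0], k=1)
    sq = 0.5 * (values[i] - values[j]) ** 2
    return d, sq, points[i] - points[j]


def empirical_variogram(
    points,
    values,
    lag_width: float | None = None,
    max_lag: float | None = None,
    direction: float | None = None,
    tolerance: float = 22.5,
) -> EmpiricalVariogram:
    """Binned empirical semivariogram, omnidirectional or directional.

    gamma_hat(h) = (1 / 2N(h)) * sum over pairs in the bin of (z_i - z_j)^2.

    Defaults: ``lag_width`` is twice the median nearest-neighbor spacing and
    ``max_lag`` half the diagonal of the point bounding box.  For a
    directional variogram, pairs are kept whose separation azimuth lies
    within ``tolerance`` degrees of ``direction`` (axes modulo 180;
    0 = E-W, 90 = N-S).  Empty bins are omitted.
    """
    points = np.asarray(points, dtype=float)
    d, sq, dxy = _pair_arrays(points, values)

    if max_lag is None:
        span = points.max(axis=0) - points.min(axis=0)
        max_lag = 0.5 * float(np.hypot(*span))
    if lag_width is None:
        lag_width = 2.0 * _median_nn_spacing(points)
    if lag_width <= 0:
        raise ValueError("lag_width must be > 0")

    keep = d <= max_lag
    if direction is not None:
        # axis of the separation vector, degrees in [0, 180)
        ang = np.degrees(np.arctan2(dxy[:, 1], dxy[:, 0])) % 180.0
        diff = np.abs(ang - (direction % 180.0))
        diff = np.minimum(diff, 180.0 - diff)
        keep &= diff <= tolerance
    d, sq = d[keep], sq[keep]
    if d.size == 0:
        raise ValueError("no point pairs within max_lag (and direction window)")

    nbins = max(int(np.ceil(max_lag / lag_width)), 1)
    idx = np.minimum((d / lag_width).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=sq, minlength=nbins)
    dsums = np.bincount(idx, weights=d, minlength=nbins)
    nonempty = counts > 0
    # lag coordinate = mean pair distance in the bin, not the nominal center:
    # clustered sampling geometries (points along tracks) otherwise bias the
    # near-origin fit, where the nugget is identified
    centers = (np.arange(nbins) + 0.5) * lag_width
    return EmpiricalVariogram(
        lags=dsums[nonempty] / counts[nonempty],
        gamma=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
        direction=direction,
        tolerance=tolerance if direction is not None else None,
        max_lag=max_lag,
        bin_centers=centers[nonempty],
    )


def _median_nn_spacing(points: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    med = float(np.median(dist[:, 1]))
    if med <= 0:
        raise ValueError("coincident points give zero nearest-neighbor spacing")
    return med


def _moment_starts(emp: EmpiricalVariogram) -> list[tuple[float, float, float]]:
    """Method-of-moments starting values for (C0, C, a), 5 spread starts."""
    sill0 = float(np.average(emp.gamma[-max(len(emp) // 3, 1):]))
    sill0 = max(sill0, float(emp.gamma.max()) * 0.5, 1e-12)
    # first lag where gamma reaches 95 % of the plateau guess
    above = np.nonzero(emp.gamma >= 0.95 * sill0)[0]
    a0 = float(emp.lags[above[0]]) if above.size else float(emp.lags[-1]) / 2.0
    a0 = max(a0, float(emp.lags[0]))
    c0_0 = max(float(emp.gamma[0]) - (sill0 - float(emp.gamma[0])) * 0.1, 0.0)
    starts = [
        (c0_0, sill0 - c0_0, a0),
        (0.0, sill0, a0),
        (0.5 * sill0, 0.5 * sill0, a0),
        (c0_0, sill0 - c0_0, a0 / 3.0),
        (c0_0, sill0 - c0_0, 3.0 * a0),
    ]
    return [(c0, max(c, 1e-12 * sill0), max(a, 1e-9)) for c0, c, a in starts]


def _fit_family(emp: EmpiricalVariogram, family: str, weights: np.ndarray) -> FitResult:
    h, g = emp.lags, emp.gamma
    w = np.sqrt(weights)

    def resid(theta):
        m = VariogramModel(family, max(theta[0], 0.0), max(theta[1], 0.0), max(theta[2], 1e-12))
        return w * (model_gamma(m, h) - g)

    hi_sill = 10.0 * float(g.max()) + 1e-12
    bounds = ([0.0, 0.0, 1e-9], [hi_sill, hi_sill, 100.0 * float(h[-1])])
    best = None
    for x0 in _moment_starts(emp):
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, x0, bounds=bounds, method="trf")
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return FitResult(
            VariogramModel(family, 0.0, float(np.var(g)) + 1e-12, float(h[-1])),
            r2=-np.inf, rss=np.inf, converged=False,
        )
    c0, c, a = best.x
    model = VariogramModel(family, float(max(c0, 0.0)), float(max(c, 0.0)), float(max(a, 1e-12)))
    pred = model_gamma(model, h)
    rss = float(np.sum(weights * (g - pred) ** 2))
    gbar = float(np.average(g, weights=weights))
    sst = float(np.sum(weights * (g - gbar) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss == 0 else -np.inf)
    return FitResult(model, r2=r2, rss=rss, converged=True)


def fit_model(
    emp: EmpiricalVariogram,
    families: Sequence[str] = FAMILIES,
    weight_mode: str = "counts",
) -> tuple[FitResult, list[FitResult]]:
    """Weighted least-squares fit of variogram model families.

    Weights default to the pair counts N(h) per bin (``counts``); the
    alternative ``counts_over_gamma2`` uses N(h)/gamma_hat(h)^2.  The best
    family maximizes R2 on the binned points, ties broken by minimum RSS.
    Returns ``(best, all_results)``.
    """
    if len(emp) < 4:
        raise ValueError("need at least 4 nonempty lag bins to fit")
    if weight_mode == "counts":
        weights = emp.counts.astype(float)
    elif weight_mode == "counts_over_gamma2":
        weights = emp.counts / np.maximum(emp.gamma, 1e-30) ** 2
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    results = []
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
        res = _fit_family(emp, fam, weights)
        if not res.converged:
            warnings.warn(f"variogram fit did not converge for family {fam!r}; skipped",
                          stacklevel=2)
        results.append(res)
    converged = [r for r in results if r.converged]
    if not converged:
        raise RuntimeError("no variogram family converged")
    best = max(converged, key=lambda r: (r.r2, -r.rss))
    return best, results


def classify_nsr(nsr: float) -> str:
    """Cambardella spatial-dependence class for a nugget-to-sill ratio."""
    if not 0.0 <= nsr <= 1.0:
        raise ValueError("NSR must be in [0, 1]")
    if nsr < 0.25:
        return "strong"
    if nsr <= 0.75:
        return "moderate"
    return "weak"


def directional_suite(
    points,
    values,
    directions: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    tolerance: float = 22.5,
    lag_width: float | None = None,
    max_lag: float | None = None,
) -> dict:
    """Directional variograms plus an anisotropy report.

    Computes one directional variogram per axis (compass semantics:
    0 = E-W, 45 = NE-SW, 90 = N-S, 135 = NW-SE) plus the omnidirectional
    curve, and flags the direction with the largest mean absolute relative
    deviation from the omnidirectional semivariance at shared lags.
    Directions with fewer than 2 pairs overall are reported as None.
    """
    omni = empirical_variogram(points, values, lag_width=lag_width, max_lag=max_lag)
    out: dict[float, EmpiricalVariogram | None] = {}
    deviation: dict[float, float] = {}
    for theta in directions:
        try:
            ev = empirical_variogram(
                points, values, lag_width=lag_width, max_lag=max_lag,
                direction=theta, tolerance=tolerance,
            )
        except ValueError:
            out[theta] = None
            continue
        out[theta] = ev
        shared = np.isin(ev.bin_centers, omni.bin_centers)
        ref = omni.gamma[np.isin(omni.bin_centers, ev.bin_centers[shared])]
        if ref.size:
            deviation[theta] = float(np.mean(np.abs(ev.gamma[shared] - ref) / np.maximum(ref, 1e-30)))
    most = max(deviation, key=deviation.get) if deviation else None
    return {
        "omnidirectional": omni,
        "directional": out,
        "deviation": deviation,
        "most_anisotropic": most,
    }


def anisotropy_ratio(g1: EmpiricalVariogram, g2: EmpiricalVariogram):
    """Anisotropy ratio K(h) = gamma_dir1(h) / gamma_dir2(h) at shared lags.

    Values near 1 at all lags indicate isotropy.  Lags where the denominator
    is zero are omitted with a warning.  Returns ``(lags, K)`` arrays.
    """
    shared = np.intersect1d(g1.bin_centers, g2.bin_centers)
    if shared.size == 0:
        raise ValueError("no overlapping lag bins between the two variograms")
    a = g1.gamma[np.isin(g1.bin_centers, shared)]
    b = g2.gamma[np.isin(g2.bin_centers, shared)]
    ok = b > 0
    if not np.all(ok):
        warnings.warn("zero-denominator lag bins omitted from anisotropy ratio",
                      stacklevel=2)
    return shared[ok], a[ok] / b[ok]
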