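"""Ordinary kriging and sequential Gaussian conditional simulation.

Ordinary kriging (OK) predicts Z*(x0) = sum_i lambda_i Z(x_i) with weights
solving the semivariogram-based system under the unbiasedness constraint
sum lambda_i = 1 (Lagrange multiplier).  It is an exact, smoothing
interpolator.

Sequential Gaussian conditional simulation (SGCS) instead draws stochastic
realizations that honor both the data and the variogram: data are mapped to
normal scores, grid nodes are visited along a random path, and at each node
a value is drawn from the simple-kriging conditional distribution given the
data *and* previously simulated nodes, then everything is back-transformed.
The pointwise mean over realizations (the E-type estimate) approaches the
kriging surface while any single realization retains the full variance the
kriging surface smooths away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .grids import GridGeometry
from .variogram import VariogramModel, model_gamma

__all__ = [
    "KrigingGrid",
    "SgcsResult",
    "NormalScoreTransform",
    "normal_scores",
    "ok_predict",
    "ok_predict_points",
    "sgcs",
    "sgcs_points",
    "etype",
    "holdout_validate",
]


@dataclass(frozen=True)
class KrigingGrid:
    """OK prediction and kriging-variance surfaces on a regular grid."""

    geometry: GridGeometry
    prediction: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if self.prediction.shape != self.geometry.shape:
            raise ValueError("prediction surface shape does not match geometry")
        if self.variance.shape != self.geometry.shape:
            raise ValueError("variance surface shape does not match geometry")


@dataclass(frozen=True)
class SgcsResult:
    """A stack of conditional realizations plus E-type summaries."""

    realizations: np.ndarray  # (n_real, nrows, ncols) or (n_real, n_points)
    etype_mean: np.ndarray
    etype_variance: np.ndarray
    seed: int
    geometry: GridGeometry | None = None

    @property
    def n_real(self) -> int:
        return self.realizations.shape[0]


class NormalScoreTransform:
    """Rank-based mapping of data to standard-normal quantiles.

    Values are assigned average ranks (ties share a rank), mapped to
    plotting positions (r - 0.5)/n and through the standard-normal quantile
    function.  The back transform interpolates linearly within the data
    range; scores beyond the observed extremes extrapolate linearly along
    the outermost segment and are clipped to ``bounds`` (defaults to the
    data min/max).
    """

    def __init__(self, values) -> None:
        v = np.asarray(values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("need at least 2 values for a normal-score transform")
        if np.ptp(v) == 0:
            raise ValueError("constant input has no normal-score transform")
        from scipy.stats import rankdata

        self._n = v.size
        ranks = rankdata(v, method="average")
        self._scores = norm.ppf((ranks - 0.5) / v.size)
        order = np.argsort(v, kind="stable")
        # dedupe ties so the back-transform table is strictly increasing
        tab_v, tab_s = [], []
        for vi, si in zip(v[order], self._scores[order]):
            if not tab_v or vi > tab_v[-1]:
                tab_v.append(vi)
                tab_s.append(si)
        self._table_values = np.asarray(tab_v)
        self._table_scores = np.asarray(tab_s)
        self._values = v

    def transform(self, values=None) -> np.ndarray:
        """Scores of the fitted sample (default) or of new values via the table."""
        if values is None:
            return self._scores.copy()
        return np.interp(np.asarray(values, dtype=float),
                         self._table_values, self._table_scores)

    def back_transform(self, scores, bounds: tuple[float, float] | None = None) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        ts, tv = self._table_scores, self._table_values
        out = np.interp(s, ts, tv)
        if ts.size >= 2:
            lo_slope = (tv[1] - tv[0]) / (ts[1] - ts[0])
            hi_slope = (tv[-1] - tv[-2]) / (ts[-1] - ts[-2])
            below = s < ts[0]
            above = s > ts[-1]
            out = np.where(below, tv[0] + (s - ts[0]) * lo_slope, out)
            out = np.where(above, tv[-1] + (s - ts[-1]) * hi_slope, out)
        lo, hi = bounds if bounds is not None else (tv[0], tv[-1])
        return np.clip(out, lo, hi)


def normal_scores(values) -> tuple[np.ndarray, NormalScoreTransform]:
    """Transform ``values`` to normal scores; returns (scores, mapping)."""
    nst = NormalScoreTransform(values)
    return nst.transform(), nst


def _dedupe(points: np.ndarray, values: np.ndarray):
    """Average values at coincident coordinates (singular-system guard)."""
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if uniq.shape[0] == points.shape[0]:
        return points, values
    warnings.warn(
        f"{points.shape[0] - uniq.shape[0]} coincident data points averaged before kriging",
        stacklevel=3,
    )
    sums = np.bincount(inverse, weights=values, minlength=uniq.shape[0])
    cnts = np.bincount(inverse, minlength=uniq.shape[0])
    return uniq, sums / cnts


def ok_predict_points(
    points,
    values,
    model: VariogramModel,
    targets,
    max_n: int = 16,
    radius: float | None = None,
    return_weight_sums: bool = False,
):
    """Ordinary kriging at arbitrary target points.

    Per target, the neighborhood is the nearest ``max_n`` data points within
    ``radius`` (default twice the model range).  Returns (predictions,
    kriging variances); targets with an empty neighborhood are NaN-masked.
    Weights sum to 1 to 1e-8 by construction of the constrained system;
    ``return_weight_sums`` appends the realized per-target sums for
    diagnostics.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("ordinary kriging needs at least 1 data point")
    points, values = _dedupe(points, values)
    if radius is None:
        radius = 2.0 * model.range_
    k = min(max_n, points.shape[0])
    tree = cKDTree(points)
    dist, idx = tree.query(targets, k=k, distance_upper_bound=radius)
    dist = np.asarray(dist).reshape(targets.shape[0], -1)
    idx = np.asarray(idx).reshape(targets.shape[0], -1)

    pred = np.full(targets.shape[0], np.nan)
    var = np.full(targets.shape[0], np.nan)
    wsum = np.full(targets.shape[0], np.nan)
    neg_var = 0
    for t in range(targets.shape[0]):
        valid = np.isfinite(dist[t])
        if not np.any(valid):
            continue
        nb = idx[t, valid]
        nb_pts = points[nb]
        m = nb.size
        # OK system: [Gamma 1; 1' 0] [lambda; mu] = [gamma0; 1]
        dmat = np.linalg.norm(nb_pts[:, None, :] - nb_pts[None, :, :], axis=-1)
        a = np.empty((m + 1, m + 1))
        a[:m, :m] = model_gamma(model, dmat)
        a[:m, m] = 1.0
        a[m, :m] = 1.0
        a[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = model_gamma(model, dist[t, valid])
        b[m] = 1.0
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        lam, mu = sol[:m], sol[m]
        pred[t] = lam @ values[nb]
        wsum[t] = lam.sum()
        v = lam @ b[:m] + mu
        if v < 0:
            neg_var += 1
            v = 0.0
        var[t] = v
    if neg_var:
        warnings.warn(f"{neg_var} numerically negative kriging variances clipped to 0",
                      stacklevel=2)
    if return_weight_sums:
        return pred, var, wsum
    return pred, var


def ok_predict(
    points,
    values,
    model: VariogramModel,
    grid: GridGeometry,
    max_n: int = 16,
    radius: float | None = None,
) -> KrigingGrid:
    """Ordinary kriging onto a regular grid; see :func:`ok_predict_points`."""
    pred, var = ok_predict_points(points, values, model, grid.node_coords(),
                                  max_n=max_n, radius=radius)
    return KrigingGrid(grid, pred.reshape(grid.shape), var.reshape(grid.shape))


def _gaussian_model(model: VariogramModel) -> VariogramModel:
    """The input model rescaled to unit sill for normal-score space."""
    nsr = model.nsr
    return VariogramModel(model.family, nsr, 1.0 - nsr, model.range_)


def _sk_conditional(gm: VariogramModel, cond_pts, cond_vals, node, max_n, radius):
    """Simple-kriging mean/variance at ``node`` (known mean 0, unit sill).

    Returns ``(mean, variance, coincident)``; ``coincident`` flags a
    conditioning point at the node itself, in which case (with zero nugget)
    the conditional distribution collapses onto that value.
    """
    from scipy.linalg import cho_factor, cho_solve

    d = np.linalg.norm(cond_pts - node, axis=1)
    within = d <= radius
    if not np.any(within):
        return 0.0, 1.0, False
    cand = np.nonzero(within)[0]
    if cand.size > max_n:
        cand = cand[np.argpartition(d[cand], max_n)[:max_n]]
    zero = cand[d[cand] == 0.0]
    if zero.size and gm.nugget == 0.0:
        return float(cond_vals[zero[0]]), 0.0, True
    nb_pts = cond_pts[cand]
    dmat = np.linalg.norm(nb_pts[:, None, :] - nb_pts[None, :, :], axis=-1)
    cmat = gm.covariance(dmat)
    cmat[np.diag_indices_from(cmat)] += 1e-9
    cvec = gm.covariance(d[cand]) * (d[cand] > 0) + (1.0 * (d[cand] == 0))
    try:
        lam = cho_solve(cho_factor(cmat, lower=True), cvec)
    except np.linalg.LinAlgError:
        lam, *_ = np.linalg.lstsq(cmat, cvec, rcond=None)
    mean = float(lam @ cond_vals[cand])
    var = float(np.clip(1.0 - lam @ cvec, 0.0, 1.0))
    return mean, var, zero.size > 0


def sgcs_points(
    points,
    values,
    model: VariogramModel,
    sim_coords,
    n_real: int = 50,
    seed: int = 0,
    max_n: int = 16,
    radius: float | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> SgcsResult:
    """Sequential Gaussian conditional simulation at arbitrary locations.

    Per realization: data are normal-score transformed; the simulation
    locations are visited along a seeded random path; each node is drawn
    from Normal(simple-kriging mean, simple-kriging variance) conditioning
    on data plus previously simulated nodes within the neighborhood; the
    realization is back-transformed, clipping to ``bounds`` (cover is a
    fraction, hence the [0, 1] default).  Realization r uses the seed
    ``seed + r`` so realizations are independent and individually
    reproducible.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    sim_coords = np.atleast_2d(np.asarray(sim_coords, dtype=float))
    points, values = _dedupe(points, values)
    if radius is None:
        radius = 2.0 * model.range_
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    scores, nst = normal_scores(values)
    gm = _gaussian_model(model)
    n_data = points.shape[0]
    n_sim = sim_coords.shape[0]
    reals = np.empty((n_real, n_sim))
    for r in range(n_real):
        rng = np.random.default_rng(seed + r)
        path = rng.permutation(n_sim)
        cond_pts = np.empty((n_data + n_sim, 2))
        cond_vals = np.empty(n_data + n_sim)
        cond_pts[:n_data] = points
        cond_vals[:n_data] = scores
        n_cond = n_data
        sim_scores = np.empty(n_sim)
        for node_idx in path:
            node = sim_coords[node_idx]
            mean, var, coincident = _sk_conditional(
                gm, cond_pts[:n_cond], cond_vals[:n_cond], node, max_n, radius)
            z = mean + np.sqrt(var) * rng.standard_normal()
            sim_scores[node_idx] = z
            if not coincident:  # a duplicate location adds no information
                cond_pts[n_cond] = node
                cond_vals[n_cond] = z
                n_cond += 1
        reals[r] = nst.back_transform(sim_scores, bounds=bounds)
    mean = reals.mean(axis=0)
    var = reals.var(axis=0)
    return SgcsResult(reals, mean, var, seed=seed, geometry=None)


def sgcs(
    points,
    values,
    model: VariogramModel,
    grid: GridGeometry,
    n_real: int = 50,
    seed: int = 0,
    max_n: int = 16,
    radius: float | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> SgcsResult:
    """SGCS over a regular grid; see :func:`sgcs_points`."""
    res = sgcs_points(points, values, model, grid.node_coords(), n_real=n_real,
                      seed=seed, max_n=max_n, radius=radius, bounds=bounds)
    shape = (res.n_real, *grid.shape)
    return SgcsResult(
        res.realizations.reshape(shape),
        res.etype_mean.reshape(grid.shape),
        res.etype_variance.reshape(grid.shape),
        seed=seed,
        geometry=grid,
    )


def etype(result: SgcsResult) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and variance surfaces across realizations."""
    return result.realizations.mean(axis=0), result.realizations.var(axis=0)


def holdout_validate(
    points,
    values,
    frac_train: float = 0.8,
    seed: int = 0,
    method: str = "ok",
    model: VariogramModel | None = None,
    n_real: int = 50,
    max_n: int = 16,
    lag_width: float | None = None,
    max_lag: float | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
):
    """Holdout validation of an interpolation method.

    Splits the data into an interpolation set (``frac_train``, default 80 %)
    and a validation set, interpolates at the held-out locations with
    ordinary kriging (``ok``) or the SGCS E-type mean (``sgcs_etype``), and
    scores observed vs. predicted.  Unless a fitted ``model`` is supplied,
    the variogram is fit on the interpolation set only.  Returns
    ``(EvalResult, table)`` with the (observed, predicted) pairs.
    """
    from .modeling import evaluate
    from .variogram import empirical_variogram, fit_model

    if not 0.0 < frac_train < 1.0:
        raise ValueError("frac_train must be strictly between 0 and 1")
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    n = points.shape[0]
    n_train = int(round(frac_train * n))
    if n_train < 4 or n - n_train < 2:
        raise ValueError("not enough points in one of the holdout parts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    if model is None:
        emp = empirical_variogram(points[tr], values[tr],
                                  lag_width=lag_width, max_lag=max_lag)
        best, _ = fit_model(emp)
        model = best.model
    if method == "ok":
        pred, _ = ok_predict_points(points[tr], values[tr], model, points[te],
                                    max_n=max_n)
        pred = np.clip(pred, *bounds)
    elif method == "sgcs_etype":
        res = sgcs_points(points[tr], values[tr], model, points[te],
                          n_real=n_real, seed=seed, max_n=max_n, bounds=bounds)
        pred = res.etype_mean
    else:
        raise ValueError(f"unknown method {method!r}")
    ok_mask = np.isfinite(pred)
    result = evaluate(values[te][ok_mask], pred[ok_mask])
    table = np.column_stack([points[te][ok_mask], values[te][ok_mask], pred[ok_mask]])
    return result, table
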