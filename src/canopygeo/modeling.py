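"""Footprint-level canopy-cover regression: screening, fitting, scoring.

Covariates are screened by two-sided Pearson correlation tests against the
canopy-cover response.  Four regressor families are available behind one
contract: a native inverse-distance-weighted k-nearest-neighbor rule
(prediction = sum w_i y_i / sum w_i over the k nearest training rows in
standardized feature space, w_i = 1/d_i, exact match returns that row's
response) and random forest / gradient boosting / support-vector
regression delegated to scikit-learn.  Predictions are clipped to [0, 1]
since cover is a fraction.

Evaluation uses RMSE with an (n-1) denominator and the coefficient of
determination R^2 = 1 - SSE/SST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

MODEL_FAMILIES = ("knn_idw", "rf", "gbrt", "svm")

__all__ = [
    "Dataset",
    "EvalResult",
    "pearson_screen",
    "KnnIdwRegressor",
    "knn_idw_predict",
    "fit_and_predict",
    "evaluate",
    "compare_models",
    "MODEL_FAMILIES",
]


@dataclass
class Dataset:
    """Feature table + response with a reproducible train/validation split."""

    features: pd.DataFrame
    response: np.ndarray
    train_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int = 0
    train_frac: float = 0.70

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        if len(self.features) != self.response.size:
            raise ValueError("features and response length mismatch")
        if self.features.isna().any().any() or np.any(~np.isfinite(self.response)):
            raise ValueError("missing values in assembled dataset")
        if self.train_mask is None:
            n = self.response.size
            rng = np.random.default_rng(self.seed)
            idx = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[idx[: int(round(self.train_frac * n))]] = True
            self.train_mask = mask
        else:
            self.train_mask = np.asarray(self.train_mask, dtype=bool)

    @property
    def x_train(self) -> np.ndarray:
        return self.features.values[self.train_mask]

    @property
    def y_train(self) -> np.ndarray:
        return self.response[self.train_mask]

    @property
    def x_val(self) -> np.ndarray:
        return self.features.values[~self.train_mask]

    @property
    def y_val(self) -> np.ndarray:
        return self.response[~self.train_mask]


@dataclass(frozen=True)
class EvalResult:
    r2: float
    rmse: float
    n: int


def pearson_screen(features: pd.DataFrame, response, alpha: float = 0.05):
    """Select covariates significantly correlated with the response.

    Runs a two-sided Pearson correlation test per column; columns with
    p < alpha are selected, ordered by |r| descending.  Constant columns
    have no defined correlation and are excluded with a warning.  Returns
    ``(selected_names, table)`` where the table has columns r, p, selected.
    """
    y = np.asarray(response, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need n >= 3 for a correlation test")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant column {name!r} excluded from screening",
                          stacklevel=2)
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = pearsonr(x, y)
        rows.append((name, float(r), float(p), bool(p < alpha)))
    table = pd.DataFrame(rows, columns=["covariate", "r", "p", "selected"])
    table = table.sort_values("r", key=lambda s: s.abs(), ascending=False,
                              na_position="last").reset_index(drop=True)
    selected = table.loc[table["selected"], "covariate"].tolist()
    return selected, table


class KnnIdwRegressor:
    """Inverse-distance-weighted k-NN in z-scored feature space.

    Features are standardized with training-set means and standard
    deviations; distances are Euclidean.  A zero-distance query returns the
    matching training response exactly (first match on ties).
    """

    def __init__(self, k: int = 5) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, x, y) -> "KnnIdwRegressor":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != y.size:
            raise ValueError("x and y length mismatch")
        if self.k > x.shape[0]:
            raise ValueError(f"k={self.k} exceeds the {x.shape[0]} training rows")
        self._mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._x = (x - self._mu) / self._sd
        self._y = y
        return self

    def predict(self, x) -> np.ndarray:
        xq = (np.atleast_2d(np.asarray(x, dtype=float)) - self._mu) / self._sd
        d = cdist(xq, self._x)
        out = np.empty(xq.shape[0])
        for i in range(xq.shape[0]):
            di = d[i]
            zero = np.nonzero(di == 0.0)[0]
            if zero.size:
                out[i] = self._y[zero[0]]
                continue
            nb = np.argpartition(di, self.k - 1)[: self.k]
            w = 1.0 / di[nb]
            out[i] = float(w @ self._y[nb] / w.sum())
        return out


def knn_idw_predict(x_train, y_train, x_query, k: int = 5) -> np.ndarray:
    """Functional form of :class:`KnnIdwRegressor`: fit then predict."""
    return KnnIdwRegressor(k=k).fit(x_train, y_train).predict(x_query)


def _make_regressor(family: str, seed: int, hyper: dict):
    if family == "knn_idw":
        return KnnIdwRegressor(**{"k": 5, **hyper})
    if family == "rf":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(random_state=seed, **hyper)
    if family == "gbrt":
        from sklearn.ensemble import GradientBoostingRegressor

        return GradientBoostingRegressor(random_state=seed, **hyper)
    if family == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR

        return make_pipeline(StandardScaler(), SVR(**hyper))
    raise ValueError(f"unknown model family {family!r}; "
                     f"choose one of {MODEL_FAMILIES}")


class _ClippedPredictor:
    """Wraps a fitted regressor so predictions stay in [0, 1]."""

    def __init__(self, inner, family: str) -> None:
        self._inner = inner
        self.family = family

    def predict(self, x) -> np.ndarray:
        return np.clip(self._inner.predict(np.atleast_2d(np.asarray(x, dtype=float))),
                       0.0, 1.0)


def fit_and_predict(train: Dataset, family: str, seed: int = 0, **hyper):
    """Fit one regressor family on the training rows of ``train``.

    Returns a predictor with a ``predict`` method whose outputs are clipped
    to [0, 1]; deterministic given (data, family, seed, hyperparameters).
    """
    reg = _make_regressor(family, seed, hyper)
    reg.fit(train.x_train, train.y_train)
    return _ClippedPredictor(reg, family)


def evaluate(y, yhat) -> EvalResult:
    """RMSE (n-1 denominator) and R^2 = 1 - SSE/SST of predictions."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need n >= 2")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in observations: R^2 undefined")
    return EvalResult(
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / (y.size - 1))),
        n=y.size,
    )


def compare_models(
    data: Dataset,
    families=MODEL_FAMILIES,
    seed: int = 0,
    hyper: dict | None = None,
) -> pd.DataFrame:
    """Fit each family on the 70 % split, score on the 30 % validation rows.

    Returns a table (method, R2, RMSE) sorted by R2 descending, mirroring
    the usual model-comparison report.
    """
    hyper = hyper or {}
    rows = []
    for fam in families:
        pred = fit_and_predict(data, fam, seed=seed, **hyper.get(fam, {}))
        res = evaluate(data.y_val, pred.predict(data.x_val))
        rows.append((fam, res.r2, res.rmse))
    return (pd.DataFrame(rows, columns=["method", "R2", "RMSE"])
            .sort_values("R2", ascending=False).reset_index(drop=True))
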