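"""Global and local Moran's I spatial autocorrelation with inference.

Global Moran's I measures whether similar attribute values cluster in
space: I > 0 indicates spatial agglomeration, I near -1/(n-1) no
autocorrelation, I < 0 dispersion.  Inference uses the Z-score under the
randomization (permutation-moment) null and, optionally, a Monte-Carlo
permutation test.  The local Moran (LISA) decomposes I into per-site
contributions I_i = z_i * lag_i / m2 and labels significant sites by
quadrant: HH/LL clusters of high/low values, HL/LH spatial outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LisaResult",
    "build_weights",
    "global_moran",
    "local_moran",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse spatial weight matrix with scheme metadata.

    ``matrix`` is an (n, n) CSR matrix with zero diagonal and nonnegative
    weights; ``row_standardized`` means each nonempty row sums to 1.
    ``isolates`` lists sites left without neighbors by the scheme.
    """

    matrix: sparse.csr_matrix
    scheme: str
    param: float
    row_standardized: bool
    isolates: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    def pairs(self) -> np.ndarray:
        """(p, q, w_pq) triplets of the nonzero weights."""
        coo = self.matrix.tocoo()
        return np.column_stack([coo.row, coo.col, coo.data])


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int
    p_perm: float | None = None


@dataclass(frozen=True)
class LisaResult:
    local_i: np.ndarray
    p: np.ndarray
    labels: np.ndarray  # 'HH', 'LL', 'HL', 'LH' or 'ns'
    alpha: float


def build_weights(
    coords,
    scheme: str = "idw_band",
    param: float | None = None,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Build a spatial weight matrix from planar site coordinates.

    Schemes
    -------
    ``band``
        Binary: w = 1 for pairs within distance ``param``.
    ``idw_band``
        Inverse distance w = 1/d for pairs within distance ``param``.
    ``knn``
        Symmetric k-nearest-neighbor (k = ``param``): w = 1 if either site
        is among the other's k nearest.

    Sites left with no neighbors are reported (with a warning) in
    ``isolates``.  Self-weights are always zero.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need >= 2 sites with planar coordinates")
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("need >= 2 distinct sites")
    n = coords.shape[0]
    tree = cKDTree(coords)
    if scheme in ("band", "idw_band"):
        if param is None or param <= 0:
            raise ValueError("distance-band schemes need a positive threshold")
        pairs = tree.query_pairs(param, output_type="ndarray")
        if pairs.size:
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            w = np.ones_like(d) if scheme == "band" else 1.0 / np.maximum(d, 1e-300)
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
            data = np.concatenate([w, w])
        else:
            rows = cols = data = np.array([])
    elif scheme == "knn":
        k = int(param) if param else 0
        if k < 1 or k >= n:
            raise ValueError("knn scheme needs 1 <= k < n")
        _, idx = tree.query(coords, k=k + 1)
        rows = np.repeat(np.arange(n), k)
        cols = idx[:, 1:].ravel()
        # symmetrize: neighbor in either direction
        mat = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        mat = mat.maximum(mat.T)
        coo = mat.tocoo()
        rows, cols, data = coo.row, coo.col, coo.data
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")

    mat = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    mat.setdiag(0.0)
    mat.eliminate_zeros()
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    isolates = tuple(np.nonzero(row_sums == 0)[0].tolist())
    if isolates:
        warnings.warn(f"{len(isolates)} sites have no neighbors under scheme "
                      f"{scheme!r} (param={param})", stacklevel=2)
    if row_standardize:
        inv = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
        mat = sparse.diags(inv) @ mat
        mat = mat.tocsr()
    return SpatialWeights(mat, scheme=scheme, param=float(param),
                          row_standardized=row_standardize, isolates=isolates)


def _deviations(values, n):
    x = np.asarray(values, dtype=float).ravel()
    if x.size != n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    if np.all(z == 0):
        raise ValueError("constant values: Moran's I undefined")
    return z


def global_moran(
    values,
    weights: SpatialWeights,
    n_perm: int = 0,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with randomization inference.

    I = (n / S0) * sum_pq w_pq z_p z_q / sum_p z_p^2 with z the deviations
    from the mean.  E(I) = -1/(n-1); Var(I) uses the randomization
    (permutation-moment) formula, robust to non-normal values.  If
    ``n_perm`` > 0, a two-sided Monte-Carlo permutation p-value is computed
    from that many random relabelings.
    """
    w = weights.matrix
    n = weights.n
    z = _deviations(values, n)
    s0 = weights.s0
    z2 = float(z @ z)
    i_obs = (n / s0) * float(z @ (w @ z)) / z2

    e_i = -1.0 / (n - 1)
    # randomization moments (Cliff & Ord)
    wt = w.T.tocsr()
    s1 = 0.5 * float(((w + wt).power(2)).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(np.sum((row + col) ** 2))
    b2 = n * float(np.sum(z**4)) / z2**2
    num = (n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
           - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2))
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    var_i = max(var_i, 0.0)
    z_score = (i_obs - e_i) / np.sqrt(var_i) if var_i > 0 else np.inf * np.sign(i_obs - e_i)
    p = 2.0 * norm.sf(abs(z_score))

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            i_p = (n / s0) * float(zp @ (w @ zp)) / z2
            if abs(i_p - e_i) >= abs(i_obs - e_i):
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return MoranResult(I=i_obs, expected=e_i, variance=var_i, z=float(z_score),
                       p=float(p), n=n, p_perm=p_perm)


def local_moran(
    values,
    weights: SpatialWeights,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> LisaResult:
    """Local Moran's I (LISA) with conditional-permutation inference.

    I_i = z_i * sum_j w_ij z_j / m2 with m2 = sum_k z_k^2 / n.  For each
    site the values at all *other* sites are randomly permuted ``n_perm``
    times while site i is held fixed; the pseudo p-value is the (folded,
    two-sided) tail probability of the observed I_i.  Significant sites
    (p < alpha) are labeled by the quadrant of (z_i, spatial lag):
    HH/LL clusters, HL/LH outliers; others are 'ns'.
    """
    w = weights.matrix
    n = weights.n
    z = _deviations(values, n)
    m2 = float(z @ z) / n
    lag = np.asarray(w @ z).ravel()
    local_i = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    indptr, indices, data = w.indptr, w.indices, w.data
    for i in range(n):
        nb_w = data[indptr[i]:indptr[i + 1]]
        if nb_w.size == 0:
            p[i] = np.nan
            continue
        others = np.delete(z, i)
        k = nb_w.size
        # each row: k draws without replacement from the other n-1 values
        pick = np.argpartition(rng.random((n_perm, others.size)), k - 1, axis=1)[:, :k]
        lags = (others[pick] * nb_w).sum(axis=1)
        sims = z[i] * lags / m2
        ge = np.count_nonzero(sims >= local_i[i])
        le = np.count_nonzero(sims <= local_i[i])
        p[i] = 2.0 * (min(ge, le) + 1) / (n_perm + 1)
    p = np.minimum(p, 1.0)

    labels = np.full(n, "ns", dtype=object)
    sig = p < alpha
    hi = z > 0
    lag_hi = lag > 0
    labels[sig & hi & lag_hi] = "HH"
    labels[sig & ~hi & ~lag_hi] = "LL"
    labels[sig & hi & ~lag_hi] = "HL"
    labels[sig & ~hi & lag_hi] = "LH"
    return LisaResult(local_i=local_i, p=p, labels=labels, alpha=alpha)
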