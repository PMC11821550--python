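"""Global and local Moran's I with k-nearest-neighbor spatial weights.

Neighborhoods are the k nearest samples by great-circle (haversine)
distance on longitude/latitude, with row-standardized weights (1/k each).
Significance uses permutation pseudo p-values: the observed statistic is
compared with ``n_perm`` random reassignments of the values over the
locations, p = (exceedances + 1) / (n_perm + 1), one-sided in the
direction of the observed deviation from the null expectation -1/(n-1).
Local Moran's I uses the conditional scheme: each location's own value is
held fixed while its neighbors' values are drawn from the remaining n-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics.pairwise import haversine_distances


@dataclass
class SpatialWeights:
    """k-nearest-neighbor row-standardized weights."""

    neighbors: np.ndarray  # (n, k) neighbor indices
    k: int
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def matrix(self) -> sparse.csr_matrix:
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        data = np.full(n * k, 1.0 / k)
        return sparse.csr_matrix(
            (data, (rows, self.neighbors.ravel())), shape=(n, n)
        )


@dataclass
class MoranResult:
    I: float
    expected: float
    pseudo_p: float | None
    n_perm: int
    permuted_I: np.ndarray | None = None
    local_I: np.ndarray | None = None
    local_pseudo_p: np.ndarray | None = None


def build_weights(sample_table: pd.DataFrame, k: int = 20) -> SpatialWeights:
    """k nearest neighbors by haversine distance on (lon, lat) degrees.

    No self-neighbors; equidistant ties are broken by sample order, so the
    neighbor sets are deterministic.  Duplicated coordinates are allowed.
    """
    lon = np.asarray(sample_table["lon"], dtype=float)
    lat = np.asarray(sample_table["lat"], dtype=float)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("coordinates must be finite")
    n = len(lon)
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    coords = np.radians(np.column_stack([lat, lon]))
    dist = haversine_distances(coords)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")  # stable: ties by index
    ids = (
        list(sample_table["sample_id"])
        if "sample_id" in sample_table
        else [str(i) for i in range(n)]
    )
    return SpatialWeights(neighbors=order[:, :k], k=k, sample_ids=ids)


def _moran_stat(z: np.ndarray, W: sparse.csr_matrix, s0: float) -> float:
    n = z.shape[0]
    return float(n / s0 * z @ (W @ z) / (z @ z))


def global_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "directed",
) -> MoranResult:
    """Global Moran's I with permutation pseudo p-value.

    ``alternative='directed'`` (default) is one-sided in the direction of
    the observed deviation from E[I] = -1/(n-1); ``'two-sided'`` doubles
    the smaller tail (capped at 1).
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if v.min() == v.max():
        raise ValueError("Moran's I undefined for constant values")
    z = v - v.mean()
    W = weights.matrix()
    s0 = float(W.sum())
    I = _moran_stat(z, W, s0)
    expected = -1.0 / (n - 1)
    if n_perm <= 0:
        return MoranResult(I, expected, None, 0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Zp = np.array([rng.permutation(z) for _ in range(n_perm)])
    denom = float(z @ z)  # invariant under permutation
    lag_p = (W @ Zp.T).T
    Ip = n / s0 * np.einsum("ij,ij->i", Zp, lag_p) / denom
    if I >= expected:
        p_dir = (np.sum(Ip >= I) + 1) / (n_perm + 1)
    else:
        p_dir = (np.sum(Ip <= I) + 1) / (n_perm + 1)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * p_dir)
    elif alternative == "directed":
        p = p_dir
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MoranResult(I, expected, float(p), n_perm, permuted_I=Ip)


def local_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MoranResult:
    """Local Moran's I_i = n * z_i * (W z)_i / sum(z^2) per sample.

    With row-standardized weights the local values sum to n times the
    global statistic.  Pseudo p-values use conditional permutation: hold
    z_i fixed, draw its k neighbor values from the other n-1 without
    replacement, one-sided in the direction of each observed local value's
    deviation from its conditional expectation.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if v.min() == v.max():
        raise ValueError("local Moran undefined for constant values")
    z = v - v.mean()
    W = weights.matrix()
    s0 = float(W.sum())
    m2 = float(z @ z)
    lag = W @ z
    local = n * z * lag / m2
    I = _moran_stat(z, W, s0)
    if n_perm <= 0:
        return MoranResult(I, -1.0 / (n - 1), None, 0, local_I=local)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = weights.k
    pvals = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        pool = z[idx != i]
        # n_perm draws of k values without replacement from the n-1 others
        u = rng.random((n_perm, n - 1))
        pick = np.argpartition(u, k, axis=1)[:, :k]
        lag_perm = pool[pick].mean(axis=1)
        local_perm = n * z[i] * lag_perm / m2
        if local[i] >= local_perm.mean():
            pvals[i] = (np.sum(local_perm >= local[i]) + 1) / (n_perm + 1)
        else:
            pvals[i] = (np.sum(local_perm <= local[i]) + 1) / (n_perm + 1)
    return MoranResult(
        I, -1.0 / (n - 1), None, n_perm, local_I=local, local_pseudo_p=pvals
    )
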