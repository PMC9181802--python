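"""Spatial covariance structures: Gaussian kernels and CAR-derived covariances.

The spatial random effect g of the model has covariance sigma^2 h^2 K, where
K is either

* a Gaussian kernel on pixel coordinates,
  ``K_ij = exp(-||s_i - s_j||^2 / (2 l^2))`` with bandwidth l, or
* the covariance implied by a conditional autoregressive (CAR) prior on an
  adjacency graph, ``K = (D - alpha_s W)^{-1}``, where W is the binary
  adjacency matrix, D = diag(m_i) holds the neighbour counts, and
  alpha_s in [0, 1) controls spatial dependence (alpha_s = 0: independence;
  alpha_s -> 1: the improper intrinsic autoregressive, IAR, limit).

The sigma^2 h^2 scaling lives in the model fit, not here.  The CAR K is not
normalised to a unit diagonal (the prior defines the covariance directly),
so h^2 values are not directly comparable across kernel kinds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors


class KernelError(ValueError):
    """Invalid kernel parameters or construction failure."""


class SingularCARError(KernelError):
    """D - alpha_s W is singular (the improper IAR limit)."""


@dataclass
class AdjacencyGraph:
    """Symmetric binary adjacency with zero diagonal, plus builder metadata."""

    W: np.ndarray
    method: str = ""
    param: float = 0.0

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise KernelError("W must be square")
        if not np.array_equal(W, W.T):
            raise KernelError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise KernelError("W must have a zero diagonal")
        if not np.all(np.isin(W, (0.0, 1.0))):
            raise KernelError("W entries must be 0 or 1")
        self.W = W

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> np.ndarray:
        """Neighbour counts m_i (row sums of W)."""
        return self.W.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.m)


@dataclass
class KernelMatrix:
    """An n x n symmetric positive-semidefinite spatial covariance structure."""

    K: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise KernelError("K must be square")
        if not np.allclose(K, K.T, atol=1e-10, rtol=0):
            raise KernelError("K must be symmetric")
        K = 0.5 * (K + K.T)
        eigs = np.linalg.eigvalsh(K)
        if eigs[0] < -1e-8 * max(eigs[-1], 1.0):
            raise KernelError(
                f"K is not positive semidefinite (min eigenvalue {eigs[0]:.3e})")
        if self.kind == "gaussian" and not np.allclose(np.diag(K), 1.0, atol=1e-12):
            raise KernelError("gaussian kernel must have a unit diagonal")
        self.K = K

    @property
    def n(self) -> int:
        return self.K.shape[0]


def build_adjacency(coords, method: str = "knn", param: float = 4) -> AdjacencyGraph:
    """Build the binary neighbourhood graph W from pixel coordinates.

    ``method="knn"``: j neighbours i if j is among i's ``param`` nearest
    neighbours or vice versa (union symmetrisation).  ``method="radius"``:
    neighbours iff Euclidean distance <= ``param``.  Pixels with no
    neighbours are allowed (m_i = 0) with a warning; duplicated coordinates
    are allowed.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise KernelError("need at least 2 pixels")
    if param <= 0:
        raise KernelError("param must be positive")
    W = np.zeros((n, n))
    if method == "knn":
        k = int(param)
        nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(coords)
        _, idx = nn.kneighbors(coords)
        for i in range(n):
            # drop self (may not be listed first when coordinates repeat)
            neigh = [j for j in idx[i] if j != i][:k]
            W[i, neigh] = 1.0
        W = np.maximum(W, W.T)
    elif method == "radius":
        dist = squareform(pdist(coords))
        W = (dist <= param).astype(float)
        np.fill_diagonal(W, 0.0)
    else:
        raise KernelError(f"unknown adjacency method {method!r}")
    isolated = int((W.sum(axis=1) == 0).sum())
    if isolated:
        warnings.warn(f"{isolated} pixel(s) have no neighbours", stacklevel=2)
    return AdjacencyGraph(W=W, method=method, param=float(param))


def gaussian_kernel(coords, bandwidth: float) -> KernelMatrix:
    """Gaussian kernel ``K_ij = exp(-||s_i - s_j||^2 / (2 bandwidth^2))``."""
    if bandwidth <= 0:
        raise KernelError("bandwidth must be positive")
    coords = np.asarray(coords, dtype=float)
    sq = squareform(pdist(coords, metric="sqeuclidean"))
    K = np.exp(-sq / (2.0 * bandwidth ** 2))
    return KernelMatrix(K=K, kind="gaussian", params={"bandwidth": float(bandwidth)})


def car_covariance(graph: AdjacencyGraph, alpha_s: float) -> KernelMatrix:
    """CAR-implied covariance ``K = (D - alpha_s W)^{-1}``.

    Isolated pixels (m_i = 0) would make D singular on their own; their
    diagonal is set to 1 so they contribute a unit, uncorrelated variance.
    ``alpha_s`` must lie in [0, 1); at 1 on a connected graph the precision
    D - W is singular (the intrinsic autoregressive, IAR, limit) and a
    :class:`SingularCARError` is raised.
    """
    if not 0.0 <= alpha_s <= 1.0:
        raise KernelError(f"alpha_s must be in [0, 1), got {alpha_s}")
    m = graph.m.copy()
    iso = m == 0
    if iso.any():
        warnings.warn(
            f"{int(iso.sum())} isolated pixel(s): CAR diagonal set to 1",
            stacklevel=2)
        m[iso] = 1.0
    M = np.diag(m) - alpha_s * graph.W
    try:
        c = cho_factor(M, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise SingularCARError(
            f"D - alpha_s W is singular at alpha_s={alpha_s}: this is the "
            "improper intrinsic autoregressive (IAR) limit; use alpha_s < 1"
        ) from exc
    if alpha_s == 1.0:
        # diagonally semidefinite cases can numerically pass Cholesky; treat
        # the exact IAR limit as singular whenever any pixel has a neighbour
        if (graph.m > 0).any():
            raise SingularCARError(
                "alpha_s = 1 is the improper intrinsic autoregressive (IAR) "
                "limit; use alpha_s < 1")
    K = cho_solve(c, np.eye(graph.n), check_finite=False)
    return KernelMatrix(K=0.5 * (K + K.T), kind="car",
                        params={"alpha_s": float(alpha_s)})


def median_nn_distance(coords) -> float:
    """Median distance from each pixel to its nearest (distinct) neighbour."""
    coords = np.asarray(coords, dtype=float)
    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return float(np.median(dist[:, 1]))


#: multipliers of the median nearest-neighbour distance used for the default
#: Gaussian bandwidth sweep -- data-adaptive scales bracketing typical ranges
DEFAULT_BANDWIDTH_SCALES = (0.5, 1.0, 2.0, 5.0, 10.0)


def default_bandwidths(coords) -> list[float]:
    """Default Gaussian bandwidth sweep for sensitivity analyses."""
    d = median_nn_distance(coords)
    if d == 0:
        d = 1.0
    return [s * d for s in DEFAULT_BANDWIDTH_SCALES]


def kernel_from_spec(coords, spec, knn: int = 4) -> KernelMatrix:
    """Build a kernel from ``("car", alpha_s)`` / ``("gaussian", bandwidth)``.

    CAR kernels use a k-nearest-neighbour adjacency (union-symmetrised,
    default k=4, a scale-free choice across heterogeneous pixel densities).
    A ready :class:`KernelMatrix` passes through unchanged.
    """
    if isinstance(spec, KernelMatrix):
        return spec
    kind, param = spec
    if kind == "car":
        graph = build_adjacency(coords, method="knn", param=knn)
        return car_covariance(graph, param)
    if kind == "gaussian":
        return gaussian_kernel(coords, param)
    raise KernelError(f"unknown kernel kind {kind!r}")
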