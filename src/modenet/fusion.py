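"""Similarity network fusion (SNF) of connectivity modes.

SNF merges several region x region similarity networks into one nonnegative
network in which edges that are consistently strong across inputs are
strengthened and inconsistent ones suppressed. For each mode, an affinity
matrix is built with a scaled exponential kernel,

    W(i, j) = exp( -rho^2(x_i, x_j) / (mu * eps_ij) ),

where x_i is region i's row profile, rho is the Euclidean distance between
profiles, and eps_ij averages each region's mean distance to its K nearest
neighbors with rho(x_i, x_j). W is normalized to a row-stochastic P (diag
1/2) and sparsified to the K strongest neighbors per row (S). The m
networks then exchange information for a fixed number of iterations:

    P(v) <- S(v) @ mean_{k != v} P(k) @ S(v)^T,

renormalizing and symmetrizing after each step; the fused network is the
elementwise mean of the converged matrices (diagonal zeroed). Default
hyperparameters: mu = 0.5, K = floor(n / 10), 20 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ConnectivityMode, upper_values

__all__ = [
    "FusionConfig",
    "FusedNetwork",
    "affinity_kernel",
    "snf_normalize",
    "knn_sparsify",
    "snf_fuse",
    "leave_one_out_robustness",
    "hyperparameter_sensitivity",
]


@dataclass
class FusionConfig:
    mu: float = 0.5
    K: int | None = None  # None -> floor(n / 10)
    n_iterations: int = 20
    epsilon_floor: float = 1e-12

    def resolve_k(self, n: int) -> int:
        k = self.K if self.K is not None else n // 10
        if not 1 <= k < n:
            raise ValueError(f"K={k} must satisfy 1 <= K < n={n}")
        return k

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FusedNetwork:
    matrix: np.ndarray  # nonnegative symmetric, zero diagonal
    config: FusionConfig
    mode_names: list[str] = field(default_factory=list)
    iteration_deltas: list[float] = field(default_factory=list)  # Frobenius per iter

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def _profile_distance_sq(mode: ConnectivityMode) -> np.ndarray:
    """Squared Euclidean distance between region row profiles, with both
    regions' self-entries removed from the comparison.

    With the diagonal zeroed, dropping columns i and j from rows i and j
    amounts to subtracting 2 x_ij^2 from the full squared distance.
    """
    x = np.nan_to_num(mode.matrix.copy())
    np.fill_diagonal(x, 0.0)
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d2 -= 2.0 * x**2
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def affinity_kernel(mode: ConnectivityMode, cfg: FusionConfig) -> np.ndarray:
    """Scaled exponential similarity kernel W for one mode."""
    n = mode.n_regions
    k = cfg.resolve_k(n)
    d2 = _profile_distance_sq(mode)
    rho = np.sqrt(d2)
    # mean distance from each region to its K nearest neighbors (self excluded)
    rho_off = rho + np.diag(np.full(n, np.inf))
    knn_mean = np.mean(np.sort(rho_off, axis=1)[:, :k], axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + rho) / 3.0
    eps = np.maximum(eps, cfg.epsilon_floor)
    return np.exp(-d2 / (cfg.mu * eps))


def snf_normalize(w: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization: P(i,j) = W(i,j) / (2 sum_{k!=i} W(i,k))
    off the diagonal, P(i,i) = 1/2. Every row sums to exactly 1."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if np.any(row <= 0):
        bad = np.flatnonzero(row <= 0)
        raise ValueError(f"zero off-diagonal row sum at regions {bad.tolist()}")
    p = off / (2.0 * row[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def knn_sparsify(w: np.ndarray, k: int) -> np.ndarray:
    """Keep the K strongest off-diagonal entries per row (ties broken by
    column index), renormalized to row-sum 1; zero elsewhere."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if not 1 <= k < n:
        raise ValueError("K out of range")
    off = w.copy()
    np.fill_diagonal(off, -np.inf)
    # stable selection: sort by (-value, column index)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -off), axis=1)
    s = np.zeros_like(w)
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    s[rows, cols] = w[rows, cols]
    sums = s.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return s / sums


def snf_fuse(
    modes: list[ConnectivityMode], cfg: FusionConfig | None = None
) -> FusedNetwork:
    """Fuse m >= 2 modes into one nonnegative network.

    All modes are updated synchronously each iteration from the previous
    iteration's values, renormalized, and symmetrized; after the fixed
    number of iterations the fused network is the mean of the m matrices.
    """
    if len(modes) < 2:
        raise ValueError("fusion needs at least 2 modes")
    cfg = cfg or FusionConfig()
    n = modes[0].n_regions
    if any(m.n_regions != n for m in modes):
        raise ValueError("modes disagree on parcellation size")
    k = cfg.resolve_k(n)
    m = len(modes)
    ws = [affinity_kernel(mode, cfg) for mode in modes]
    ps = [snf_normalize(w) for w in ws]
    ss = [knn_sparsify(w, k) for w in ws]
    deltas = []
    for _ in range(cfg.n_iterations):
        total = np.sum(ps, axis=0)
        new_ps = []
        for v in range(m):
            others = (total - ps[v]) / (m - 1)
            pv = ss[v] @ others @ ss[v].T
            pv = snf_normalize(pv)
            pv = (pv + pv.T) / 2.0
            new_ps.append(pv)
        deltas.append(float(np.sqrt(sum(np.sum((a - b) ** 2) for a, b in zip(new_ps, ps)))))
        ps = new_ps
    fused = np.mean(ps, axis=0)
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 0.0)
    return FusedNetwork(
        matrix=fused,
        config=cfg,
        mode_names=[mo.mode_name for mo in modes],
        iteration_deltas=deltas,
    )


def _spearman_upper(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.spearmanr(upper_values(a), upper_values(b)).statistic)


def leave_one_out_robustness(
    modes: list[ConnectivityMode], cfg: FusionConfig | None = None
) -> dict:
    """Spearman correlation of each leave-one-out fusion with the full
    fusion (upper triangles); reports the per-mode values and the minimum."""
    if len(modes) < 3:
        raise ValueError("leave-one-out needs at least 3 modes")
    cfg = cfg or FusionConfig()
    full = snf_fuse(modes, cfg).matrix
    rs = {}
    for v in range(len(modes)):
        subset = [mo for idx, mo in enumerate(modes) if idx != v]
        rs[modes[v].mode_name] = _spearman_upper(snf_fuse(subset, cfg).matrix, full)
    return {"per_mode": rs, "min": min(rs.values())}


def hyperparameter_sensitivity(
    modes: list[ConnectivityMode],
    k_range: list[int],
    mu_range: list[float],
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Spearman correlation of each (K, mu) fusion with the default fusion;
    grid shape |k_range| x |mu_range|."""
    cfg = cfg or FusionConfig()
    n = modes[0].n_regions
    for k in k_range:
        if not 1 <= k < n:
            raise ValueError(f"K={k} out of [1, n-1]")
    base = snf_fuse(modes, cfg).matrix
    grid = np.empty((len(k_range), len(mu_range)))
    for i, k in enumerate(k_range):
        for j, mu in enumerate(mu_range):
            alt = FusionConfig(mu=mu, K=k, n_iterations=cfg.n_iterations,
                               epsilon_floor=cfg.epsilon_floor)
            grid[i, j] = _spearman_upper(snf_fuse(modes, alt).matrix, base)
    return grid
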