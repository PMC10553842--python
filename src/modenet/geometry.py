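"""Distance-decay characterization and structure-similarity coupling.

Feature similarity between cortical regions falls off with distance; this
module fits that decay (exponential vs. linear, selected by R^2), removes it
(residualization used as a control in the disease-exposure analysis), bins
rank-transformed edges by distance, and tests whether structurally connected
region pairs are more similar than unconnected pairs against degree- and
edge-length-preserving surrogate connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import ConnectivityMode, EdgeTable, StructuralConnectome, embed_upper, upper_values

__all__ = [
    "DecayFit",
    "fit_distance_decay",
    "regress_distance",
    "binned_median_rank",
    "structural_coupling_test",
    "connected_weight_correlation",
]

# multi-start grid for the exponential rate; guards against local minima
_B_STARTS = (-0.001, -0.01, -0.05, -0.1, -0.5)


@dataclass
class DecayFit:
    """Fit of edge weight vs. distance: y = a*exp(b*d) + c and y = s*d + i."""

    exp_params: tuple[float, float, float] | None  # (a, b, c)
    lin_params: tuple[float, float]  # (slope, intercept)
    r2_exp: float
    r2_lin: float
    selected: str  # {"exponential", "linear"}
    degenerate: bool = False
    exp_converged: bool = True

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.selected == "exponential" and self.exp_params is not None:
            a, b, c = self.exp_params
            return a * np.exp(b * d) + c
        s, i = self.lin_params
        return s * d + i


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return -np.inf
    return 1.0 - ss_res / ss_tot


def fit_distance_decay(
    mode: ConnectivityMode | np.ndarray, dist: np.ndarray
) -> DecayFit:
    """Fit edge weight against distance with both candidate forms.

    The exponential y = a*exp(b*d) + c is fit by nonlinear least squares from
    five starting rates; the linear form by ordinary least squares. The form
    with the higher R^2 on the same edge set is selected. If no exponential
    start converges, the linear fit is returned with a flag.
    """
    matrix = mode.matrix if isinstance(mode, ConnectivityMode) else np.asarray(mode)
    y = upper_values(matrix)
    d = upper_values(np.asarray(dist, dtype=float))
    keep = np.isfinite(y)
    y, d = y[keep], d[keep]

    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0]) if y.size else 0.0
        return DecayFit(None, (slope, intercept), -np.inf, -np.inf, "linear", degenerate=True)

    lin = stats.linregress(d, y)
    lin_params = (float(lin.slope), float(lin.intercept))
    r2_lin = _r2(y, lin.slope * d + lin.intercept)

    def f(d_, a, b, c):
        return a * np.exp(b * d_) + c

    best = None
    for b0 in _B_STARTS:
        a0 = float(y[np.argsort(d)[: max(1, y.size // 50)]].mean() - y.min()) or 1.0
        c0 = float(y.min())
        try:
            popt, _ = optimize.curve_fit(
                f, d, y, p0=(a0, b0, c0), maxfev=5000, ftol=1e-10, xtol=1e-10
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((y - f(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)

    if best is None:
        return DecayFit(None, lin_params, -np.inf, r2_lin, "linear", exp_converged=False)

    popt = best[1]
    r2_exp = _r2(y, f(d, *popt))
    selected = "exponential" if r2_exp > r2_lin else "linear"
    return DecayFit(tuple(map(float, popt)), lin_params, r2_exp, r2_lin, selected)


def regress_distance(
    mode: ConnectivityMode, dist: np.ndarray, fit: DecayFit | None = None
) -> tuple[ConnectivityMode, float]:
    """Residualize a mode on its distance-decay fit.

    Returns the residual mode (symmetric re-embedding) and the Spearman
    correlation of the residual edges with distance (a diagnostic; near zero
    when the fit captured the decay).
    """
    if fit is None:
        fit = fit_distance_decay(mode, dist)
    y = upper_values(mode.matrix)
    d = upper_values(np.asarray(dist, dtype=float))
    resid = y - fit.predict(d)
    keep = np.isfinite(resid)
    rho = float(stats.spearmanr(resid[keep], d[keep]).statistic) if keep.sum() > 2 else np.nan
    out = ConnectivityMode(
        embed_upper(resid, mode.n_regions), mode_name=f"{mode.mode_name}_distresid"
    )
    return out, rho


def binned_median_rank(
    table: EdgeTable, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Median edge rank in equal-count bins of increasing distance.

    Edges are sorted by distance and split into n_bins equal-count bins; the
    remainder (E mod n_bins) goes to the last, longest-distance bin. Returns
    (median distance per bin, median rank per bin).
    """
    if table.distance is None:
        raise ValueError("edge table has no distances")
    e = table.n_edges
    if n_bins > e:
        raise ValueError("more bins than edges")
    order = np.argsort(table.distance, kind="stable")
    size = e // n_bins
    med_d = np.empty(n_bins)
    med_r = np.empty(n_bins)
    for b in range(n_bins):
        start = b * size
        stop = (b + 1) * size if b < n_bins - 1 else e
        idx = order[start:stop]
        med_d[b] = np.median(table.distance[idx])
        med_r[b] = np.median(table.rank[idx])
    return med_d, med_r


def structural_coupling_test(
    mode: ConnectivityMode,
    sc: StructuralConnectome,
    nulls: list[StructuralConnectome] | None = None,
) -> dict:
    """Are structurally connected pairs more similar than unconnected pairs?

    delta = mean(mode weight | connected) - mean(mode weight | unconnected).
    If surrogate connectomes are given (degree- and edge-length-preserving
    rewirings), delta is recomputed on each and
    p_null = (1 + #{delta_null >= delta}) / (1 + n_null).
    """
    w = upper_values(mode.matrix)
    adj = upper_values(sc.adjacency.astype(float)) > 0
    if not adj.any() or adj.all():
        raise ValueError("need at least one connected and one unconnected edge")
    finite = np.isfinite(w)

    def _delta(a: np.ndarray) -> float:
        return float(w[a & finite].mean() - w[~a & finite].mean())

    delta = _delta(adj)
    result = {
        "mean_connected": float(w[adj & finite].mean()),
        "mean_unconnected": float(w[~adj & finite].mean()),
        "delta": delta,
        "p_null": None,
    }
    if nulls:
        null_deltas = np.array(
            [_delta(upper_values(s.adjacency.astype(float)) > 0) for s in nulls]
        )
        result["p_null"] = float((1 + np.sum(null_deltas >= delta)) / (1 + len(nulls)))
        result["null_deltas"] = null_deltas
    return result


def connected_weight_correlation(
    mode: ConnectivityMode, sc: StructuralConnectome
) -> float:
    """Spearman correlation between structural weight and mode weight over
    the structurally connected edges."""
    w = upper_values(mode.matrix)
    sw = upper_values(sc.weights)
    mask = (sw > 0) & np.isfinite(w)
    if mask.sum() < 10:
        raise ValueError("need at least 10 connected edges")
    return float(stats.spearmanr(sw[mask], w[mask]).statistic)
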