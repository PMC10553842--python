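"""Construction of connectivity modes from regional data.

A connectivity mode is a region x region network whose edges encode how
similarly two regions present a biological feature (gene expression profile,
receptor density profile, laminar intensity profile) or how strongly their
signals co-fluctuate (haemodynamic, metabolic, electrophysiological time
series). Four constructions are provided:

* :func:`feature_similarity` — Pearson correlation of regional feature rows;
* :func:`partial_feature_similarity` — Pearson correlation of regional
  profiles after regressing out the across-region mean profile (used for
  laminar intensity profiles);
* :func:`timeseries_connectivity` — Pearson correlation between regional
  time series;
* :func:`composite_pc1` — first principal component of several modes'
  vectorized upper triangles, re-embedded as a matrix (used to summarize
  band-specific electrophysiological networks).

Supporting utilities implement the robust-sigmoid normalization, donor-wise
differential stability with its retention threshold, and the Fisher r-to-z
transform applied to every finished mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .core import ConnectivityMode, embed_upper, upper_values

__all__ = [
    "DonorExpressionSet",
    "NormalizationRecord",
    "robust_sigmoid",
    "zscore_features",
    "differential_stability",
    "filter_by_stability",
    "feature_similarity",
    "partial_feature_similarity",
    "timeseries_connectivity",
    "composite_pc1",
    "fisher_z",
]

# IQR of a standard normal; dividing the IQR by this scales it to an
# SD-equivalent spread, the convention for the robust sigmoid.
_NORMAL_IQR = 1.35
_CLIP = 1e-7


@dataclass
class DonorExpressionSet:
    """Per-donor region x feature matrices sharing one feature space.

    Missing regions in a donor are encoded as NaN rows; donor pairs are
    compared on their common (finite) region subset.
    """

    donors: list[np.ndarray]
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.donors = [np.asarray(d, dtype=float) for d in self.donors]
        n_feat = {d.shape[1] for d in self.donors}
        if len(n_feat) != 1:
            raise ValueError("all donors must share the same feature space")
        if self.feature_ids is None:
            self.feature_ids = [f"f{i}" for i in range(self.donors[0].shape[1])]

    @property
    def n_donors(self) -> int:
        return len(self.donors)


@dataclass
class NormalizationRecord:
    method: str
    median: np.ndarray | float | None = None
    iqr: np.ndarray | float | None = None
    degenerate: bool = False


def robust_sigmoid(x: np.ndarray) -> tuple[np.ndarray, NormalizationRecord]:
    """Outlier-robust sigmoidal normalization, rescaled to the unit interval.

    ``x_norm = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))`` followed by
    min-max rescaling to [0, 1]. An all-equal input (IQR = 0) returns the
    pre-rescale constant 0.5 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("robust_sigmoid needs at least 2 values")
    med = float(np.median(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0.0:
        return np.full_like(x, 0.5), NormalizationRecord(
            "robust_sigmoid", med, 0.0, degenerate=True
        )
    norm = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / _NORMAL_IQR)))
    lo, hi = norm.min(), norm.max()
    scaled = (norm - lo) / (hi - lo) if hi > lo else np.full_like(norm, 0.5)
    return scaled, NormalizationRecord("robust_sigmoid", med, iqr)


def zscore_features(features: np.ndarray) -> np.ndarray:
    """Z-score each feature (column) across regions (receptor-style input)."""
    f = np.asarray(features, dtype=float)
    sd = f.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (f - f.mean(axis=0)) / sd


def differential_stability(dset: DonorExpressionSet) -> np.ndarray:
    """Mean over donor pairs of the Spearman correlation of each feature's
    regional profile; values in [-1, 1], one per feature.

    Donor pairs with missing regions are compared on the common subset
    (>= 3 shared regions required per pair).
    """
    if dset.n_donors < 2:
        raise ValueError("differential stability needs at least 2 donors")
    n_feat = dset.donors[0].shape[1]
    acc = np.zeros(n_feat)
    n_pairs = 0
    for a, b in combinations(dset.donors, 2):
        common = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
        if common.sum() < 3:
            raise ValueError("a donor pair shares fewer than 3 regions")
        ra = stats.rankdata(a[common], axis=0)
        rb = stats.rankdata(b[common], axis=0)
        ra = ra - ra.mean(axis=0)
        rb = rb - rb.mean(axis=0)
        denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
        denom[denom == 0] = np.nan
        acc += (ra * rb).sum(axis=0) / denom
        n_pairs += 1
    return acc / n_pairs


def filter_by_stability(
    dset: DonorExpressionSet, threshold: float = 0.1
) -> tuple[list[str], np.ndarray]:
    """Retain features whose differential stability strictly exceeds the
    threshold (default 0.1). Returns (retained feature ids, boolean mask)."""
    ds = differential_stability(dset)
    mask = ds > threshold
    kept = [fid for fid, keep in zip(dset.feature_ids, mask) if keep]
    return kept, mask


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows yield NaN edges."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ss = np.sqrt((xc**2).sum(axis=1))
    bad = ss == 0
    ss_safe = np.where(bad, 1.0, ss)
    r = (xc @ xc.T) / np.outer(ss_safe, ss_safe)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r


def feature_similarity(
    features: np.ndarray, method: str = "pearson", mode_name: str = "feature_similarity"
) -> ConnectivityMode:
    """Region x region Pearson correlation of regional feature profiles
    (pre-Fisher). Zero-variance regions produce NaN edges and are reported
    via ValueError only if *all* rows are degenerate."""
    if method != "pearson":
        raise ValueError(f"unsupported method {method!r}")
    f = np.asarray(features, dtype=float)
    if f.shape[1] < 3:
        raise ValueError("feature similarity needs at least 3 features")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature matrix must be finite")
    r = _pearson_rows(f)
    if np.all(np.isnan(upper_values(r))):
        raise ValueError("all regions degenerate (zero variance)")
    np.fill_diagonal(r, 1.0)
    return ConnectivityMode(r, mode_name=mode_name)


def partial_feature_similarity(
    features: np.ndarray, mode_name: str = "partial_similarity"
) -> ConnectivityMode:
    """Partial correlation between regional profiles controlling for the
    across-region mean profile.

    Each region's profile is regressed (with intercept) on the mean profile
    across regions; the residual profiles are then correlated pairwise.
    """
    f = np.asarray(features, dtype=float)
    if f.shape[1] < 4:
        raise ValueError("partial similarity needs at least 4 features")
    mean_profile = f.mean(axis=0)
    g = mean_profile - mean_profile.mean()
    denom = float(g @ g)
    fc = f - f.mean(axis=1, keepdims=True)
    if denom == 0:
        resid = fc
    else:
        beta = fc @ g / denom
        resid = fc - np.outer(beta, g)
    r = _pearson_rows(resid)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMode(r, mode_name=mode_name)


def timeseries_connectivity(
    ts: np.ndarray, mode_name: str = "timeseries_connectivity"
) -> ConnectivityMode:
    """Pearson correlation between regional time series (pre-Fisher)."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    r = _pearson_rows(ts)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMode(r, mode_name=mode_name)


@dataclass
class CompositeResult:
    mode: ConnectivityMode
    loadings: np.ndarray  # per input mode, loading on PC1
    var_explained: np.ndarray  # % per component


def composite_pc1(
    modes: list[ConnectivityMode], mode_name: str = "composite_pc1"
) -> CompositeResult:
    """First principal component of several modes' vectorized upper
    triangles, re-embedded as a symmetric matrix.

    PCA sign is arbitrary, so PC1 is oriented to correlate positively with
    the elementwise mean of the inputs.
    """
    if len(modes) < 2:
        raise ValueError("composite needs at least 2 modes")
    n = modes[0].n_regions
    if any(m.n_regions != n for m in modes):
        raise ValueError("modes disagree on parcellation size")
    X = np.column_stack([upper_values(m.matrix) for m in modes])  # E x m
    Xc = X - X.mean(axis=0)
    # SVD of the edge x mode matrix: PC scores live in edge space
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    var = s**2 / np.sum(s**2) * 100.0
    mean_edge = X.mean(axis=1)
    orient = np.corrcoef(scores, mean_edge)[0, 1]
    sign = -1.0 if orient < 0 else 1.0
    scores *= sign
    loadings = vt[0] * sign
    matrix = embed_upper(scores, n, diagonal=0.0)
    return CompositeResult(
        mode=ConnectivityMode(matrix, mode_name=mode_name),
        loadings=loadings,
        var_explained=var,
    )


def fisher_z(
    mode: ConnectivityMode | np.ndarray, mode_name: str | None = None
) -> ConnectivityMode:
    """Fisher r-to-z transform, z = arctanh(r), applied elementwise.

    Values at exactly +-1 are clipped to +-(1 - 1e-7) before the transform;
    |r| > 1 + 1e-9 raises.
    """
    if isinstance(mode, ConnectivityMode):
        r = mode.matrix
        name = mode_name or mode.mode_name
    else:
        r = np.asarray(mode, dtype=float)
        name = mode_name or "mode"
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1 + 1e-9):
        raise ValueError("correlation matrix has |r| > 1")
    clipped = np.clip(r, -1.0 + _CLIP, 1.0 - _CLIP)
    z = np.arctanh(clipped)
    return ConnectivityMode(z, mode_name=name)
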