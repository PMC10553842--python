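"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates parcellated cortical data at desk scale:

* a bilateral parcellation whose two hemispheres mirror in x, with unit-
  sphere centroid projections and two independent spatial partitions
  (7 "intrinsic" classes, 4 "cytoarchitectonic" classes);
* multimodal region x feature matrices drawn from a spatial Gaussian
  process with covariance exp(-d/lambda), mixing a latent pool shared
  across modes (weight alpha controls the cross-mode edge correlation)
  with mode-specific draws, and with homotopic (mirror-pair) latent
  sharing so interhemispheric homologues are elevated in similarity;
* a distance-dependent structural connectome with a hub tail in the
  degree distribution, capable of expressing rich-club organization;
* region x time Gaussian time series with a requested spatial covariance;
* regional abnormality maps generated from the disease-exposure model
  itself, for parameter-recovery testing.

All randomness flows from a single integer seed expanded into named
substreams (order: parcellation, shared latents, per-mode latents, noise,
connectome, time series, abnormality), so outputs are bit-reproducible and
stable as the generator grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import ConnectivityMode, Parcellation, StructuralConnectome, AbnormalityMap
from .core import pairwise_distance

__all__ = [
    "SynthConfig",
    "make_parcellation",
    "make_feature_matrix",
    "make_structural_connectome",
    "make_timeseries",
    "make_abnormality",
]

# substream ids, appended to the user seed in a SeedSequence
_STREAMS = {
    "parcellation": 0,
    "shared_latents": 1,
    "mode_latents": 2,
    "feature_noise": 3,
    "connectome": 4,
    "timeseries": 5,
    "abnormality": 6,
}

# weight with which a right-hemisphere region inherits its mirror partner's
# latent features; elevates homotopic similarity without forcing identity
_HOMOTOPY_WEIGHT = 0.8

# propensity multiplier for hub regions in the structural connectome
_HUB_PROPENSITY = 3.0


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, extra)])
    )


@dataclass
class SynthConfig:
    """Study conditions for the synthetic suite.

    Defaults are the desk-scale conditions every stage is exercised under:
    200 regions, 7 modes, spatial autocorrelation length 15 mm,
    shared-latent weight 0.2 and feature noise 0.9 (jointly calibrated so
    the median inter-mode edge correlation sits near 0.25 while distance
    decay and homotopic elevation stay visible), structural density 0.15
    with distance decay 0.02/mm and a 10% hub fraction.
    """

    n_regions: int = 200
    n_modes: int = 7
    n_features_per_mode: int = 60
    spatial_scale: float = 15.0  # mm, GP autocorrelation length (lambda)
    shared_latent_weight: float = 0.2  # alpha in [0, 1]
    sc_density: float = 0.15
    sc_distance_decay: float = 0.02  # eta, 1/mm
    hub_fraction: float = 0.1
    noise_sd: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be >= 10")
        if self.n_regions % 2:
            raise ValueError("n_regions must be even (two hemispheres)")
        if not 0.0 <= self.shared_latent_weight <= 1.0:
            raise ValueError("shared_latent_weight must be in [0, 1]")
        if not 0.0 < self.sc_density < 1.0:
            raise ValueError("sc_density must be in (0, 1)")
        if not 0.0 <= self.hub_fraction <= 0.5:
            raise ValueError("hub_fraction must be in [0, 0.5]")
        if self.spatial_scale < 0 or self.noise_sd < 0 or self.sc_distance_decay < 0:
            raise ValueError("spatial_scale, noise_sd, sc_distance_decay must be >= 0")
        if self.n_modes < 1 or self.n_features_per_mode < 3:
            raise ValueError("need n_modes >= 1 and n_features_per_mode >= 3")


def make_parcellation(cfg: SynthConfig) -> Parcellation:
    """Two mirror-symmetric hemispheres of n/2 regions each.

    Left-hemisphere centroids lie on a flat sheet at negative x; the right
    hemisphere is the exact x-mirror. Spherical centroids are obtained by
    mapping the sheet coordinates to longitude/latitude on the unit sphere,
    one hemisphere per x half-space, with a short row of medial-wall proxy
    points along the medial (interhemispheric) boundary.

    Intrinsic labels come from a 7-way k-means partition of the left-
    hemisphere sheet (mirrored to the right); cytoarchitectonic labels from
    an independent 4-way partition.
    """
    rng = _rng(cfg.seed, "parcellation")
    half = cfg.n_regions // 2

    # 2-D sheet in (y, z), embedded at x = -30 mm
    y = rng.uniform(-80.0, 60.0, size=half)
    z = rng.uniform(-40.0, 60.0, size=half)
    left_mm = np.column_stack([np.full(half, -30.0), y, z])
    right_mm = left_mm * np.array([-1.0, 1.0, 1.0])

    # map sheet -> sphere: longitude in the x<0 half, latitude from z
    lon = np.pi / 2 + 0.15 + (y + 80.0) / 140.0 * (np.pi - 0.3)
    lat = -np.pi / 2 + 0.15 + (z + 40.0) / 100.0 * (np.pi - 0.3)
    left_sph = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
    right_sph = left_sph * np.array([-1.0, 1.0, 1.0])

    # medial-wall proxies: points at the longitudinal boundaries of each
    # hemisphere's spherical patch
    t = np.linspace(-np.pi / 2 + 0.2, np.pi / 2 - 0.2, 6)
    wall = []
    for lon_w in (np.pi / 2 + 0.05, 3 * np.pi / 2 - 0.05):
        pts = np.column_stack(
            [np.cos(t) * np.cos(lon_w), np.cos(t) * np.sin(lon_w), np.sin(t)]
        )
        wall.append(pts)
        wall.append(pts * np.array([-1.0, 1.0, 1.0]))
    wall = np.vstack(wall)
    wall /= np.linalg.norm(wall, axis=1, keepdims=True)

    sheet = np.column_stack([y, z])
    km7 = KMeans(n_clusters=min(7, half), n_init=4,
                 random_state=int(rng.integers(2**31)))
    intrinsic_half = km7.fit_predict(sheet)
    km4 = KMeans(n_clusters=min(4, half), n_init=4,
                 random_state=int(rng.integers(2**31)))
    cyto_half = km4.fit_predict(sheet)

    ids = [f"L_{i}" for i in range(half)] + [f"R_{i}" for i in range(half)]
    return Parcellation(
        region_ids=ids,
        centroid_mm=np.vstack([left_mm, right_mm]),
        centroid_sphere=np.vstack([left_sph, right_sph]),
        hemisphere=np.array(["L"] * half + ["R"] * half),
        intrinsic_label=np.concatenate([intrinsic_half, intrinsic_half]),
        cyto_label=np.concatenate([cyto_half, cyto_half]),
        medial_wall_sphere=wall,
    )


def _gp_coloring(parc: Parcellation, spatial_scale: float) -> np.ndarray:
    """Square root of the GP kernel exp(-d/lambda) via eigen-decomposition
    with eigenvalue clipping at 0 (the kernel can be numerically indefinite).
    lambda = 0 degenerates to white noise (identity kernel)."""
    n = parc.n_regions
    if spatial_scale <= 0:
        return np.eye(n)
    d = pairwise_distance(parc, "mm")
    k = np.exp(-d / spatial_scale)
    w, v = np.linalg.eigh(k)
    # symmetric square root: keeps the latent index region-aligned, so
    # homotopic latent sharing survives the spatial coloring
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _homotopy_mix(draws: np.ndarray, half: int) -> np.ndarray:
    """Blend mirror-pair latents: right region r = 0.8 * left partner +
    sqrt(1 - 0.8^2) * own draw, preserving unit variance."""
    out = draws.copy()
    h = _HOMOTOPY_WEIGHT
    out[half:] = h * draws[:half] + np.sqrt(1.0 - h**2) * draws[half:]
    return out


def make_feature_matrix(
    parc: Parcellation, cfg: SynthConfig, mode_index: int
) -> np.ndarray:
    """Region x feature matrix for one mode.

    Each column is a draw from the spatial GP; a fraction alpha of its
    variance comes from a latent pool shared by all modes, the rest from
    mode-specific draws. Homotopic region pairs share latent values, and
    optional white measurement noise (cfg.noise_sd) is added on top.
    """
    if mode_index >= cfg.n_modes or mode_index < 0:
        raise ValueError(f"mode_index {mode_index} out of range [0, {cfg.n_modes})")
    n, half = parc.n_regions, parc.n_regions // 2
    L = _gp_coloring(parc, cfg.spatial_scale)
    shared = _rng(cfg.seed, "shared_latents").standard_normal((n, cfg.n_features_per_mode))
    own = _rng(cfg.seed, "mode_latents", mode_index).standard_normal(
        (n, cfg.n_features_per_mode)
    )
    a = cfg.shared_latent_weight
    latent = np.sqrt(a) * shared + np.sqrt(1.0 - a) * own
    latent = _homotopy_mix(latent, half)
    feats = L @ latent
    if cfg.noise_sd > 0:
        noise = _rng(cfg.seed, "feature_noise", mode_index).standard_normal(feats.shape)
        feats = feats + cfg.noise_sd * noise
    return feats


def make_structural_connectome(
    parc: Parcellation, cfg: SynthConfig, max_retries: int = 20
) -> StructuralConnectome:
    """Distance-dependent random connectome with degree hubs.

    Edge (i, j) appears with probability proportional to
    exp(-eta * d_ij) * g_i * g_j, where g is 1 for ordinary regions and a
    heavy-tailed propensity for ceil(hub_fraction * n) hub regions. The
    proportionality constant is solved (bisection on clipped probabilities)
    so the expected density equals sc_density; draws are retried until the
    realized density lands within 10% of the request. Present edges receive
    rank-uniform weights in (0, 1], ordered by the underlying edge score so
    that short, hub-adjacent connections are the strongest.
    """
    rng = _rng(cfg.seed, "connectome")
    n = parc.n_regions
    d = pairwise_distance(parc, "mm")
    g = np.ones(n)
    n_hubs = ceil(cfg.hub_fraction * n)
    if n_hubs:
        hubs = rng.choice(n, size=n_hubs, replace=False)
        g[hubs] = _HUB_PROPENSITY
    score = np.exp(-cfg.sc_distance_decay * d) * np.outer(g, g)
    np.fill_diagonal(score, 0.0)
    iu = np.triu_indices(n, k=1)
    s = score[iu]

    def realized(c: float) -> float:
        return float(np.mean(np.clip(c * s, 0.0, 1.0)))

    lo, hi = 0.0, 1.0
    while realized(hi) < cfg.sc_density:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("requested density unreachable under the distance decay")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < cfg.sc_density:
            lo = mid
        else:
            hi = mid
    p = np.clip(hi * s, 0.0, 1.0)

    target = cfg.sc_density
    for _ in range(max_retries):
        present = rng.random(s.size) < p
        dens = present.mean()
        if abs(dens - target) <= 0.1 * target:
            break
    else:
        raise ValueError("could not realize the requested density within 10%")

    weights_flat = np.zeros(s.size)
    e = int(present.sum())
    # rank-uniform weights in (0, 1], ordered by edge score (ties jittered)
    order_score = s[present] + rng.normal(0.0, 1e-12, size=e)
    ranks = stats.rankdata(order_score, method="ordinal")
    weights_flat[present] = ranks / e
    w = np.zeros((n, n))
    w[iu] = weights_flat
    w += w.T
    return StructuralConnectome(w)


def make_timeseries(
    parc: Parcellation,
    cfg: SynthConfig,
    target_cov: np.ndarray,
    n_timepoints: int,
) -> np.ndarray:
    """Gaussian region x time samples with the requested spatial covariance."""
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    c = np.asarray(target_cov, dtype=float)
    if c.shape != (parc.n_regions, parc.n_regions):
        raise ValueError("target_cov shape must match the parcellation")
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(f"target covariance is not PSD (min eigenvalue {w.min():.3g})")
    L = v * np.sqrt(np.clip(w, 0.0, None))
    rng = _rng(cfg.seed, "timeseries")
    return L @ rng.standard_normal((parc.n_regions, n_timepoints))


def make_abnormality(
    mode: ConnectivityMode,
    noise_sd: float,
    seed: int,
    disorder_name: str = "synthetic",
    n_iterations: int = 3,
) -> AbnormalityMap:
    """Abnormality map generated by inverting the disease-exposure model.

    Starting from a random regional vector, iterate
    d <- zscore(C+ d / rowcount+) (3 iterations), where C+ keeps only the
    mode's positive edges; then add Gaussian noise of sd noise_sd and
    z-score. With small noise, the exposure computed from the mode
    correlates with the map by construction — the parameter-recovery target.
    """
    c = mode.matrix.copy()
    np.fill_diagonal(c, 0.0)
    cpos = np.clip(np.nan_to_num(c), 0.0, None)
    counts = (cpos > 0).sum(axis=1)
    if not counts.any():
        raise ValueError("mode has no positive edges")
    rng = _rng(seed, "abnormality")
    d = rng.standard_normal(mode.n_regions)
    safe = np.where(counts > 0, counts, 1)
    for _ in range(n_iterations):
        d = cpos @ d / safe
        d = (d - d.mean()) / d.std()
    d = d + noise_sd * rng.standard_normal(d.size)
    d = (d - d.mean()) / d.std()
    return AbnormalityMap(values=d, disorder_name=disorder_name)
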