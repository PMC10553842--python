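"""Null models: spin permutations and distance-binned degree-preserving rewiring.

Two nulls recur throughout the analysis:

* **Spin tests** assess correlations between regional maps while preserving
  spatial autocorrelation: parcel centroids on the spherical surface are
  randomly rotated (each hemisphere separately, the right hemisphere using
  the mirror-conjugated rotation) and each original parcel is reassigned the
  value of the nearest rotated parcel. Parcels for which a medial-wall proxy
  is nearest take the next most proximal parcel instead.

* **Rewired surrogates** preserve the density, degree sequence, and binned
  edge-length distribution of a structural connectome: edges are binned by
  Euclidean distance and degree-preserving double-edge swaps are performed
  within bins only, with swaps producing self-loops, multi-edges, or edges
  leaving the bin rejected and redrawn. With a single bin this degenerates
  to plain Maslov-Sneppen rewiring, which is the null used for the
  rich-club ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .core import Parcellation, StructuralConnectome

__all__ = [
    "SpinPermutations",
    "RewiredEnsemble",
    "spin_permutations",
    "spin_correlation",
    "rewire_preserving",
]

logger = logging.getLogger(__name__)

_X_MIRROR = np.diag([-1.0, 1.0, 1.0])
_SWAP_RETRY_CAP = 100


@dataclass
class SpinPermutations:
    """Nearest-parcel reassignments under random sphere rotations.

    perm_index[k, i] gives the source parcel whose rotated position is
    nearest original parcel i — a permuted map is map[perm_index[k]]. Rows
    need not be permutations: nearest-parcel reassignment can repeat values.
    """

    perm_index: np.ndarray  # (n_rotations, n_regions)
    n_rotations: int
    seed: int | None = None
    wall_hits: int = 0  # times a medial-wall proxy was the nearest candidate


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via the quaternion method."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def spin_permutations(
    parc: Parcellation,
    n_rotations: int = 10000,
    seed: int | None = None,
    rotations: list[np.ndarray] | None = None,
) -> SpinPermutations:
    """Build spatial-rotation reassignments on the spherical centroids.

    One uniform random rotation is drawn per repetition for the left
    hemisphere; the right hemisphere uses the same rotation conjugated by an
    x-reflection so homotopy is respected. Reassignment is within-hemisphere
    nearest rotated parcel; where the parcellation carries medial-wall proxy
    points and one of them is nearest, the next most proximal rotated parcel
    is used instead. ``rotations`` is a test hook replacing the random draws
    (e.g. the identity, which must give the identity reassignment).
    """
    if parc.centroid_sphere is None:
        raise ValueError("spin tests need spherical centroids")
    rng = np.random.default_rng(seed)
    coords = parc.centroid_sphere
    hemis = parc.hemisphere
    n = parc.n_regions
    if rotations is not None:
        n_rotations = len(rotations)

    wall = parc.medial_wall_sphere
    perm = np.empty((n_rotations, n), dtype=int)
    wall_hits = 0
    for k in range(n_rotations):
        rot_l = rotations[k] if rotations is not None else _random_rotation(rng)
        rot_r = _X_MIRROR @ rot_l @ _X_MIRROR
        for hemi, rot in (("L", rot_l), ("R", rot_r)):
            idx = np.flatnonzero(hemis == hemi)
            pts = coords[idx]
            rotated = pts @ rot.T
            candidates = rotated
            n_parcels = idx.size
            if wall is not None and wall.size:
                wall_h = wall[(wall[:, 0] < 0) == (hemi == "L")]
                candidates = np.vstack([rotated, wall_h @ rot.T])
            d = cdist(pts, candidates)
            nearest = np.argmin(d, axis=1)
            hit = nearest >= n_parcels
            wall_hits += int(hit.sum())
            if hit.any():
                # next most proximal parcel: nearest among actual parcels
                nearest[hit] = np.argmin(d[hit][:, :n_parcels], axis=1)
            perm[k, idx] = idx[nearest]
    return SpinPermutations(perm, n_rotations, seed, wall_hits)


def spin_correlation(
    map_a: np.ndarray, map_b: np.ndarray, perms: SpinPermutations
) -> dict:
    """Pearson correlation of two regional maps with a two-sided spin p-value.

    The null distribution correlates the spun map_a against the intact
    map_b; p_spin = (1 + #{|r_null| >= |r|}) / (1 + n_rotations).
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size or a.size != perms.perm_index.shape[1]:
        raise ValueError("maps and permutations disagree on region count")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    spun = a[perms.perm_index]  # (n_rot, n)
    sc = spun - spun.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((sc**2).sum(axis=1)) * np.sqrt((bc**2).sum())
    with np.errstate(invalid="ignore"):
        r_null = (sc @ bc) / denom
    r_null = np.nan_to_num(r_null)
    p = float((1 + np.sum(np.abs(r_null) >= abs(r))) / (1 + perms.n_rotations))
    return {"r": r, "p_spin": p, "r_null": r_null}


@dataclass
class RewiredEnsemble:
    networks: list[StructuralConnectome]
    n_bins: int
    n_swaps: int
    seed: int | None = None
    shortfalls: list[int] = field(default_factory=list)  # failed swaps per surrogate


def _bin_matrix(dist: np.ndarray, edge_d: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin id for every node pair, from equal-count quantile bounds of the
    source network's edge distances."""
    if n_bins == 1:
        return np.zeros_like(dist, dtype=int)
    bounds = np.quantile(edge_d, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(dist, bounds)


def rewire_preserving(
    sc: StructuralConnectome,
    dist: np.ndarray,
    n_bins: int = 10,
    swap_factor: int = 20,
    n_surrogates: int = 1,
    seed: int | None = None,
) -> RewiredEnsemble:
    """Degree- and edge-length-preserving surrogate connectomes.

    Edges are binned by Euclidean distance (equal-count bins over the source
    edges); within each bin, random pairs of edges are double-edge-swapped,
    for swap_factor * n_regions swaps in total per surrogate. A swap is
    rejected (and redrawn, up to a bounded number of retries) if it would
    create a self-loop or multi-edge or if either new edge's distance falls
    outside the bin. Swapped edges carry their weights with them, so the
    weight multiset is preserved alongside the degree sequence and the
    binned edge-length histogram.
    """
    rng = np.random.default_rng(seed)
    n = sc.n_regions
    dist = np.asarray(dist, dtype=float)
    iu = np.triu_indices(n, k=1)
    adj0 = sc.adjacency.astype(bool)
    edges0 = np.column_stack([iu[0][adj0[iu]], iu[1][adj0[iu]]])
    edge_d = dist[edges0[:, 0], edges0[:, 1]]
    bin_of = _bin_matrix(dist, edge_d, n_bins)
    n_swaps = swap_factor * n

    networks: list[StructuralConnectome] = []
    shortfalls: list[int] = []
    for _ in range(n_surrogates):
        adj = adj0.copy()
        w = sc.weights.copy()
        by_bin: list[list[tuple[int, int]]] = [[] for _ in range(n_bins)]
        for i, j in edges0:
            by_bin[bin_of[i, j]].append((int(i), int(j)))
        usable = [b for b in range(n_bins) if len(by_bin[b]) >= 2]
        skipped = [b for b in range(n_bins) if len(by_bin[b]) < 2]
        if skipped:
            logger.warning("bins with < 2 edges skipped: %s", skipped)
        if not usable:
            networks.append(StructuralConnectome(w))
            shortfalls.append(n_swaps)
            continue
        counts = np.array([len(by_bin[b]) for b in usable], dtype=float)
        cum = np.cumsum(counts / counts.sum())
        failed = 0
        for _ in range(n_swaps):
            done = False
            for _ in range(_SWAP_RETRY_CAP):
                b = usable[int(np.searchsorted(cum, rng.random()))]
                bucket = by_bin[b]
                e1 = int(rng.integers(len(bucket)))
                e2 = int(rng.integers(len(bucket)))
                if e1 == e2:
                    continue
                a, bb = bucket[e1]
                c, d = bucket[e2]
                if rng.random() < 0.5:
                    c, d = d, c
                # propose (a,d) and (c,bb)
                if len({a, bb, c, d}) < 4:
                    continue
                p1 = (min(a, d), max(a, d))
                p2 = (min(c, bb), max(c, bb))
                if adj[p1] or adj[p2]:
                    continue
                if bin_of[p1] != b or bin_of[p2] != b:
                    continue
                w1 = w[bucket[e1]]
                w2 = w[bucket[e2]]
                adj[a, bb] = adj[bb, a] = False
                adj[c, d] = adj[d, c] = False
                w[a, bb] = w[bb, a] = 0.0
                w[c, d] = w[d, c] = 0.0
                adj[p1] = adj[p1[::-1]] = True
                adj[p2] = adj[p2[::-1]] = True
                w[p1] = w[p1[::-1]] = w1
                w[p2] = w[p2[::-1]] = w2
                bucket[e1] = p1
                bucket[e2] = p2
                done = True
                break
            if not done:
                failed += 1
        shortfalls.append(failed)
        networks.append(StructuralConnectome(w))
    if any(shortfalls):
        logger.warning(
            "rewiring fell short of %d swaps by %.1f on average over %d surrogates",
            n_swaps, float(np.mean(shortfalls)), n_surrogates,
        )
    return RewiredEnsemble(networks, n_bins, n_swaps, seed, shortfalls)
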