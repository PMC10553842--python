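"""Core domain types and shared utilities.

The package operates on parcellated cortical data: a :class:`Parcellation`
describes the regions (centroids, hemispheres, categorical labels), a
:class:`ConnectivityMode` is a symmetric region x region similarity network
(Fisher-z units), a :class:`StructuralConnectome` is a weighted white-matter
network scaled to [0, 1], and an :class:`AbnormalityMap` carries regional
z-scored case-vs-control effect sizes. All modules downstream consume these
types.

Region indexing is 0-based internally. The diagonal of a connectivity mode is
undefined (self-similarity has no meaning across modes) and is excluded from
every edge statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "Parcellation",
    "ConnectivityMode",
    "StructuralConnectome",
    "EdgeTable",
    "AbnormalityMap",
    "pairwise_distance",
    "rank_edges",
    "upper_values",
    "embed_upper",
]

_SYMMETRY_TOL = 1e-10


def _as_2d(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return m


@dataclass
class Parcellation:
    """Regions of a cortical parcellation with coordinates and labels.

    Parameters
    ----------
    region_ids : sequence of str
        Ordered region identifiers.
    centroid_mm : (n, 3) array
        Region centroids in millimetres.
    centroid_sphere : (n, 3) array, optional
        Unit vectors on the spherical surface projection; required only by
        spin tests.
    hemisphere : (n,) array of {"L", "R"}
    intrinsic_label : (n,) array, optional
        Intrinsic functional network membership (7 canonical classes).
    cyto_label : (n,) array, optional
        Cytoarchitectonic class membership.
    medial_wall_sphere : (k, 3) array, optional
        Unit-vector proxies for medial-wall locations, used by the spin
        test's reassignment rule.
    """

    region_ids: list[str]
    centroid_mm: np.ndarray
    hemisphere: np.ndarray
    centroid_sphere: np.ndarray | None = None
    intrinsic_label: np.ndarray | None = None
    cyto_label: np.ndarray | None = None
    medial_wall_sphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region_ids = [str(r) for r in self.region_ids]
        n = len(self.region_ids)
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)
        if self.centroid_mm.shape != (n, 3):
            raise ValueError("centroid_mm must be (n_regions, 3)")
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        if self.hemisphere.shape != (n,):
            raise ValueError("hemisphere must have one entry per region")
        bad = set(np.unique(self.hemisphere)) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be L or R, got {bad}")
        if self.centroid_sphere is not None:
            self.centroid_sphere = np.asarray(self.centroid_sphere, dtype=float)
            if self.centroid_sphere.shape != (n, 3):
                raise ValueError("centroid_sphere must be (n_regions, 3)")
            norms = np.linalg.norm(self.centroid_sphere, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("centroid_sphere rows must have unit norm")
        for name in ("intrinsic_label", "cyto_label"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape != (n,):
                    raise ValueError(f"{name} must have one entry per region")
                setattr(self, name, lab)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def __len__(self) -> int:
        return self.n_regions


@dataclass
class ConnectivityMode:
    """Symmetric region x region similarity matrix (Fisher-z units).

    The diagonal is undefined and never enters edge statistics; it is kept in
    storage (as whatever the constructor received) but flagged through
    ``diagonal_defined=False``.
    """

    matrix: np.ndarray
    mode_name: str = "mode"
    diagonal_defined: bool = False

    def __post_init__(self) -> None:
        m = _as_2d(self.matrix)
        off = ~np.eye(m.shape[0], dtype=bool)
        if np.any(np.isinf(m[off])):
            raise ValueError(f"mode '{self.mode_name}' has infinite off-diagonal entries")
        # NaN edges (from degenerate zero-variance regions) are tolerated but
        # must be symmetric; they are reported through nan_edges.
        if not np.allclose(m, m.T, atol=_SYMMETRY_TOL, rtol=0.0, equal_nan=True):
            raise ValueError(f"mode '{self.mode_name}' is not symmetric within {_SYMMETRY_TOL}")
        self.matrix = m

    @property
    def nan_edges(self) -> np.ndarray:
        """(k, 2) indices of undefined off-diagonal edges (i < j)."""
        nan = np.isnan(self.matrix)
        np.fill_diagonal(nan, False)
        idx = np.argwhere(np.triu(nan, k=1))
        return idx

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StructuralConnectome:
    """Weighted structural connectome, weights scaled to [0, 1].

    ``adjacency`` is the binary support (weights > 0) and ``degree`` the
    number of structural connections per region.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = _as_2d(self.weights)
        if np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
            raise ValueError("structural weights must be symmetric")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("structural weights must lie in [0, 1]")
        if np.any(np.diag(w) != 0):
            raise ValueError("structural connectome must have a zero diagonal")
        self.weights = w

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(int)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class AbnormalityMap:
    """Regional z-scored case-versus-control effect sizes for one disorder."""

    values: np.ndarray
    disorder_name: str = "disorder"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("abnormality values must be finite")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass
class EdgeTable:
    """Upper-triangular edge list of one mode with values, ranks, distances.

    Ranks run from 1 (most negative edge) to E (most positive), ties
    averaged, so that edge strengths are comparable across modes.
    """

    edge_index: np.ndarray  # (E, 2), i < j, 0-based
    value: np.ndarray
    rank: np.ndarray
    distance: np.ndarray | None = None
    n_regions: int = 0

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]


def upper_values(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle (row-major edge order)."""
    m = _as_2d(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def embed_upper(values: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Re-embed an upper-triangular edge vector as a symmetric matrix."""
    values = np.asarray(values, dtype=float)
    out = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    if values.size != iu[0].size:
        raise ValueError("edge vector length does not match n(n-1)/2")
    out[iu] = values
    out[(iu[1], iu[0])] = values
    return out


def pairwise_distance(parc: Parcellation, which: str = "mm") -> np.ndarray:
    """Pairwise interregional distance matrix.

    ``which="mm"`` gives Euclidean distance between millimetre centroids.
    ``which="sphere-geodesic"`` gives great-circle arc length on the unit
    sphere, a packaged stand-in where true surface geodesics are unavailable.
    """
    if which == "mm":
        return squareform(pdist(parc.centroid_mm))
    if which == "sphere-geodesic":
        if parc.centroid_sphere is None:
            raise ValueError("parcellation has no spherical centroids")
        dots = np.clip(parc.centroid_sphere @ parc.centroid_sphere.T, -1.0, 1.0)
        d = np.arccos(dots)
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown distance space {which!r}")


def rank_edges(
    mode: ConnectivityMode | np.ndarray,
    distance: np.ndarray | None = None,
) -> EdgeTable:
    """Rank-transform the edges of a mode (1 = most negative, E = most positive).

    Ties receive the average rank, which preserves the rank-sum identity
    sum(rank) = E(E+1)/2.
    """
    matrix = mode.matrix if isinstance(mode, ConnectivityMode) else _as_2d(mode)
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    values = matrix[iu]
    ranks = rankdata(values, method="average")
    dist = None
    if distance is not None:
        dist = _as_2d(distance)[iu]
    return EdgeTable(
        edge_index=np.column_stack(iu),
        value=values,
        rank=ranks,
        distance=dist,
        n_regions=n,
    )
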