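"""Rich-club analysis, hubness, and intra-class edge profiling.

The rich club is the subnetwork among regions whose structural degree meets
a threshold k; its density is compared with degree-preserving surrogates
(the rich-club coefficient *ratio*). Rich links — structurally supported
edges joining two high-degree regions — are profiled in each connectivity
mode by their median edge rank against all other supported edges (one-sided
Welch test). Hubness of a region in a mode is the sum of its incident
rank-transformed edge weights; cross-modal hubness is the median across
modes. Intra-class fractions measure how many of a mode's strongest edges
join two regions sharing a categorical label.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats

from .core import ConnectivityMode, EdgeTable, StructuralConnectome
from .nulls import RewiredEnsemble

__all__ = [
    "RichClubProfile",
    "rich_club_coefficient",
    "rich_club_ratio",
    "rich_link_rank",
    "top_edges",
    "hubness",
    "cross_modal_hubness",
    "cross_modal_edge_rank",
    "intra_class_fraction",
]


@dataclass
class RichClubProfile:
    k_grid: np.ndarray
    phi: np.ndarray
    phi_null_mean: np.ndarray
    ratio: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # boolean per k (p <= 0.05)


def rich_club_coefficient(adjacency: np.ndarray, k: int) -> float:
    """Density of the subgraph of nodes with degree >= k.

    phi(k) = 2 E_k / (n_k (n_k - 1)); NaN where fewer than 2 nodes qualify.
    Computed on the binary network.
    """
    adj = np.asarray(adjacency) > 0
    deg = adj.sum(axis=1)
    nodes = deg >= k
    nk = int(nodes.sum())
    if nk < 2:
        return float("nan")
    ek = int(adj[np.ix_(nodes, nodes)].sum()) // 2
    return 2.0 * ek / (nk * (nk - 1))


def rich_club_ratio(
    sc: StructuralConnectome,
    k_grid: np.ndarray | range,
    nulls: RewiredEnsemble | list[StructuralConnectome],
) -> RichClubProfile:
    """Rich-club coefficient ratio with significance against rewired nulls.

    ratio(k) = phi(k) / mean(phi_null(k)) over plain degree-preserving
    surrogates (single-bin rewiring). Significance per k uses
    p = (1 + #{ratio_null >= ratio}) / (1 + n_null), where each surrogate's
    ratio_null is its phi against the ensemble mean.
    """
    k_grid = np.asarray(list(k_grid), dtype=int)
    networks = nulls.networks if isinstance(nulls, RewiredEnsemble) else nulls
    n_null = len(networks)
    adj = sc.adjacency
    phi = np.array([rich_club_coefficient(adj, k) for k in k_grid])
    phi_null = np.array(
        [[rich_club_coefficient(s.adjacency, k) for k in k_grid] for s in networks]
    )  # (n_null, n_k)
    with np.errstate(invalid="ignore"):
        null_mean = np.array(
            [np.nanmean(col) if np.any(np.isfinite(col)) else np.nan
             for col in phi_null.T]
        )
        ratio = phi / null_mean
        ratio_null = phi_null / null_mean
        exceed = np.nansum(ratio_null >= ratio, axis=0)
    p = (1 + exceed) / (1 + n_null)
    p = np.where(np.isfinite(ratio), p, np.nan)
    sig = np.where(np.isfinite(ratio), p <= 0.05, False)
    return RichClubProfile(k_grid, phi, null_mean, ratio, p, sig)


def rich_link_rank(
    sc: StructuralConnectome, mode_table: EdgeTable, k: int
) -> dict:
    """Median mode edge rank of rich links vs. other structurally supported
    edges, with a one-sided two-sample Welch t-test (rich > other)."""
    deg = sc.degree
    adj = sc.adjacency
    i, j = mode_table.edge_index[:, 0], mode_table.edge_index[:, 1]
    supported = adj[i, j] > 0
    rich = supported & (deg[i] >= k) & (deg[j] >= k)
    other = supported & ~rich
    if not rich.any() or not other.any():
        return {
            "median_rank_rich": float("nan"),
            "median_rank_other": float("nan"),
            "p_welch": float("nan"),
        }
    rr = mode_table.rank[rich]
    ro = mode_table.rank[other]
    t = stats.ttest_ind(rr, ro, equal_var=False, alternative="greater")
    return {
        "median_rank_rich": float(np.median(rr)),
        "median_rank_other": float(np.median(ro)),
        "p_welch": float(t.pvalue),
    }


def top_edges(mode: ConnectivityMode | EdgeTable, pct: float) -> np.ndarray:
    """Indices (into the upper-triangular edge list) of the ceil(pct% * E)
    strongest edges; ties broken by (i, j) lexicographic order."""
    if pct <= 0 or pct > 100:
        raise ValueError("pct must be in (0, 100]")
    from .core import rank_edges

    table = mode if isinstance(mode, EdgeTable) else rank_edges(mode)
    e = table.n_edges
    n_top = ceil(pct / 100.0 * e)
    # lexsort: primary key descending value, then ascending (i, j)
    order = np.lexsort(
        (table.edge_index[:, 1], table.edge_index[:, 0], -table.value)
    )
    return order[:n_top]


def hubness(mode_table: EdgeTable) -> np.ndarray:
    """Per-region sum of the ranks of its incident edges."""
    out = np.zeros(mode_table.n_regions)
    np.add.at(out, mode_table.edge_index[:, 0], mode_table.rank)
    np.add.at(out, mode_table.edge_index[:, 1], mode_table.rank)
    return out


def cross_modal_hubness(mode_tables: list[EdgeTable]) -> np.ndarray:
    """Elementwise median of per-mode hubness vectors."""
    if len(mode_tables) < 2:
        raise ValueError("cross-modal hubness needs at least 2 modes")
    return np.median(np.stack([hubness(t) for t in mode_tables]), axis=0)


def cross_modal_edge_rank(mode_tables: list[EdgeTable]) -> EdgeTable:
    """Per-edge median of per-mode ranks, as a new edge table."""
    if len(mode_tables) < 2:
        raise ValueError("cross-modal edge rank needs at least 2 modes")
    e = mode_tables[0].n_edges
    if any(t.n_edges != e for t in mode_tables):
        raise ValueError("edge tables disagree on parcellation")
    med = np.median(np.stack([t.rank for t in mode_tables]), axis=0)
    ref = mode_tables[0]
    return EdgeTable(
        edge_index=ref.edge_index,
        value=med,
        rank=stats.rankdata(med, method="average"),
        distance=ref.distance,
        n_regions=ref.n_regions,
    )


def intra_class_fraction(
    mode: ConnectivityMode | EdgeTable,
    labels: np.ndarray,
    pcts: np.ndarray | list[float] | None = None,
    combine: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of the top-pct strongest edges joining two same-label regions.

    With ``combine`` given (a second labeling), an edge counts only when its
    endpoints share BOTH labels — the conjunction used to ask whether a
    network's strongest edges respect intrinsic networks and
    cytoarchitectonic classes simultaneously. Returns (pcts, fractions).
    """
    from .core import rank_edges

    table = mode if isinstance(mode, EdgeTable) else rank_edges(mode)
    labels = np.asarray(labels)
    if labels.size != table.n_regions:
        raise ValueError("labels must cover all regions")
    if pcts is None:
        pcts = np.arange(0.5, 5.01, 0.5)
    pcts = np.asarray(pcts, dtype=float)
    i, j = table.edge_index[:, 0], table.edge_index[:, 1]
    same = labels[i] == labels[j]
    if combine is not None:
        combine = np.asarray(combine)
        same = same & (combine[i] == combine[j])
    order = np.lexsort((table.edge_index[:, 1], table.edge_index[:, 0], -table.value))
    fractions = np.empty(pcts.size)
    for p_idx, pct in enumerate(pcts):
        n_top = ceil(pct / 100.0 * table.n_edges)
        fractions[p_idx] = float(same[order[:n_top]].mean())
    return pcts, fractions
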