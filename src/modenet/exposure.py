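"""Network disease-exposure model.

Disease exposure asks whether a region's abnormality (z-scored case-versus-
control cortical-thickness effect size) reflects the abnormality of the
regions it is similar to. For a connectivity mode C and abnormality map d,

    D_i = (1 / N_i) * sum_{j != i} d_j * c_ij,

computed by default over the positive edges of region i only (N_i = number
of positive connections). Variants swap the weighting:

* ``negative_edges`` — only c_ij < 0 edges enter (dissimilarity exposure);
* ``structural``     — weighted structural connectivity, structurally
  connected regions only;
* ``distance``       — inverse Euclidean distance, all regions;
* ``all_edges``      — the positive-edge mask is dropped, N_i = n - 1.

The summary statistic is the Spearman correlation between exposure and
abnormality across regions (NaN regions excluded pairwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbnormalityMap, ConnectivityMode, StructuralConnectome
from .geometry import DecayFit, regress_distance

__all__ = ["ExposureResult", "exposure", "exposure_panel", "VARIANTS"]

VARIANTS = ("positive_edges", "negative_edges", "structural", "distance", "all_edges")


@dataclass
class ExposureResult:
    exposure: np.ndarray  # D_i, abnormality units; NaN where no valid edges
    n_edges: np.ndarray  # N_i per region
    rho: float  # Spearman(exposure, abnormality) over valid regions
    variant: str
    constant: bool = False  # exposure constant -> rho undefined


def _weight_matrix(
    variant: str,
    mode: ConnectivityMode | None,
    sc: StructuralConnectome | None,
    dist: np.ndarray | None,
) -> np.ndarray:
    if variant in ("positive_edges", "negative_edges", "all_edges"):
        if mode is None:
            raise ValueError(f"variant {variant!r} needs a connectivity mode")
        c = np.nan_to_num(mode.matrix.copy())
        np.fill_diagonal(c, 0.0)
        if variant == "positive_edges":
            c[c < 0] = 0.0
        elif variant == "negative_edges":
            c[c > 0] = 0.0
        return c
    if variant == "structural":
        if sc is None:
            raise ValueError("structural variant needs a structural connectome")
        return sc.weights.copy()
    if variant == "distance":
        if dist is None:
            raise ValueError("distance variant needs a distance matrix")
        d = np.asarray(dist, dtype=float).copy()
        np.fill_diagonal(d, np.inf)
        return 1.0 / d
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def exposure(
    mode: ConnectivityMode | None,
    ab: AbnormalityMap,
    variant: str = "positive_edges",
    sc: StructuralConnectome | None = None,
    dist: np.ndarray | None = None,
) -> ExposureResult:
    """Disease exposure D_i and its Spearman correlation with abnormality.

    Regions with no qualifying edge (N_i = 0) get NaN exposure and are
    excluded from the correlation. A variant whose weights are empty
    everywhere (e.g. negative_edges on an all-positive mode) raises.
    """
    c = _weight_matrix(variant, mode, sc, dist)
    d = ab.values
    n = d.size
    if c.shape != (n, n):
        raise ValueError("mode and abnormality map disagree on parcellation")
    if variant == "negative_edges":
        counts = (c < 0).sum(axis=1)
    elif variant == "all_edges":
        counts = np.full(n, n - 1)
    else:
        counts = (c > 0).sum(axis=1)
    if not counts.any():
        raise ValueError(f"variant {variant!r}: no qualifying edges anywhere")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = (c @ d) / counts
    D = np.where(counts > 0, D, np.nan)
    valid = np.isfinite(D)
    constant = bool(valid.sum() >= 2 and np.ptp(D[valid]) == 0)
    if valid.sum() < 3 or constant or np.ptp(d[valid]) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(D[valid], d[valid]).statistic)
    return ExposureResult(D, counts, rho, variant, constant)


def exposure_panel(
    modes: list[ConnectivityMode],
    abnormality_maps: list[AbnormalityMap],
    sc: StructuralConnectome | None = None,
    dist: np.ndarray | None = None,
    distance_regressed: bool = False,
    include_all_edges: bool = False,
) -> pd.DataFrame:
    """Disorder x predictor table of exposure-abnormality Spearman rho.

    Predictors are the given modes plus, when supplied, the structural and
    inverse-distance baselines. ``distance_regressed`` residualizes each
    mode on its own distance-decay fit first; ``include_all_edges`` drops
    the positive-edge mask. Per-cell failures propagate as NaN; the panel
    never aborts.
    """
    used_modes = modes
    if distance_regressed:
        if dist is None:
            raise ValueError("distance_regressed needs a distance matrix")
        used_modes = [regress_distance(m, dist)[0] for m in modes]
    variant = "all_edges" if include_all_edges else "positive_edges"

    columns: list[tuple[str, dict]] = [
        (m.mode_name, {"mode": m, "variant": variant}) for m in used_modes
    ]
    if sc is not None:
        columns.append(("structural", {"mode": None, "variant": "structural"}))
    if dist is not None:
        columns.append(("distance", {"mode": None, "variant": "distance"}))

    rows = {}
    for ab in abnormality_maps:
        row = {}
        for name, kw in columns:
            try:
                row[name] = exposure(kw["mode"], ab, kw["variant"], sc=sc, dist=dist).rho
            except ValueError:
                row[name] = float("nan")
        rows[ab.disorder_name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
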