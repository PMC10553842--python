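"""End-to-end pipeline: synthesize -> build modes -> analyze -> fuse -> report.

The pipeline runs every analysis stage on a synthetic suite (or, with file
inputs via the library API, on user-supplied matrices) and serializes a
machine-readable JSON report: distance-decay fits, structure-similarity
coupling deltas and null p-values, the rich-club profile, hubness vectors,
the disease-exposure panel, gradient variance spectra, community counts,
and fusion robustness. All randomness flows from one global seed.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import geometry, gradients, richclub
from .core import pairwise_distance, rank_edges
from .exposure import exposure_panel
from .fusion import FusionConfig, hyperparameter_sensitivity, leave_one_out_robustness, snf_fuse
from .io import save_centroids, save_labels, save_matrix
from .modes import feature_similarity, fisher_z
from .nulls import rewire_preserving, spin_correlation, spin_permutations
from .synth import SynthConfig, make_abnormality, make_feature_matrix, \
    make_parcellation, make_structural_connectome

__all__ = ["RunConfig", "run_pipeline", "build_synthetic_suite"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; every block mirrors one stage's parameters."""

    seed: int = 0
    out_dir: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "geometry": True,
            "richclub": True,
            "exposure": True,
            "gradients": True,
            "communities": True,
            "fusion": True,
            "spin": True,
        }
    )
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    geometry_params: dict = field(
        default_factory=lambda: {"n_bins": 50, "n_coupling_nulls": 100}
    )
    richclub_params: dict = field(
        default_factory=lambda: {"k_min": 5, "k_max": 50, "n_nulls": 100}
    )
    exposure_params: dict = field(
        default_factory=lambda: {"n_disorders": 3, "abnormality_noise_sd": 1.0}
    )
    communities_params: dict = field(
        default_factory=lambda: {
            "gamma": 1.0,
            "n_reps": 50,
            "sweep_gammas": [0.5, 1.0, 2.0, 3.0],
            "sweep_reps": 20,
        }
    )
    fusion_params: dict = field(
        default_factory=lambda: {
            "mu": 0.5,
            "K": None,
            "n_iterations": 20,
            "sensitivity_k": [],
            "sensitivity_mu": [],
        }
    )
    spin_params: dict = field(default_factory=lambda: {"n_rotations": 1000})

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in raw.items():
            if isinstance(value, dict) and isinstance(getattr(base, key), dict):
                merged = dict(getattr(base, key))
                bad = set(value) - set(merged) if key != "synth" else set()
                if bad:
                    raise ValueError(f"unknown keys in [{key}]: {sorted(bad)}")
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base


def _clean(obj):
    """Make a report JSON-safe: numpy -> python, non-finite -> null+reason."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else {"value": None, "reason": "non-finite"}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_synthetic_suite(cfg: SynthConfig) -> dict:
    """Generate the full synthetic study: parcellation, distance matrices,
    Fisher-z connectivity modes, structural connectome."""
    parc = make_parcellation(cfg)
    dist = pairwise_distance(parc, "mm")
    modes = []
    for v in range(cfg.n_modes):
        feats = make_feature_matrix(parc, cfg, v)
        modes.append(fisher_z(feature_similarity(feats, mode_name=f"mode_{v}")))
    sc = make_structural_connectome(parc, cfg)
    return {"parcellation": parc, "distance": dist, "modes": modes, "sc": sc}


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute the enabled stages in dependency order; return (and
    optionally write) the report bundle."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_toml(config)
    t0 = time.time()
    report: dict = {"config": {"seed": config.seed}, "stages": {}, "timing_s": {}}
    rng = np.random.default_rng(config.seed)

    synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
    t = time.time()
    suite = build_synthetic_suite(synth_cfg)
    parc, dist, modes, sc = (
        suite["parcellation"], suite["distance"], suite["modes"], suite["sc"],
    )
    tables = [rank_edges(m, dist) for m in modes]
    report["config"]["synth"] = asdict(synth_cfg)
    report["timing_s"]["synth"] = time.time() - t
    logger.info("synth: n=%d, %d modes", parc.n_regions, len(modes))

    from .core import upper_values

    edge_stack = np.column_stack([upper_values(m.matrix) for m in modes])
    inter = np.corrcoef(edge_stack, rowvar=False)
    iu = np.triu_indices(len(modes), k=1)
    report["stages"]["intermode"] = {
        "median_r": float(np.median(inter[iu])),
        "min_r": float(inter[iu].min()),
        "max_r": float(inter[iu].max()),
    }

    coupling_nulls = None
    if config.stages.get("geometry", True):
        t = time.time()
        gp = config.geometry_params
        n_bins = min(gp["n_bins"], tables[0].n_edges)
        coupling_nulls = rewire_preserving(
            sc, dist, n_bins=10, n_surrogates=gp["n_coupling_nulls"],
            seed=int(rng.integers(2**31)),
        ).networks
        block = {}
        for m, tab in zip(modes, tables):
            fit = geometry.fit_distance_decay(m, dist)
            med_d, med_r = geometry.binned_median_rank(tab, n_bins=n_bins)
            coup = geometry.structural_coupling_test(m, sc, coupling_nulls)
            coup.pop("null_deltas", None)
            block[m.mode_name] = {
                "decay": {
                    "selected": fit.selected,
                    "exp_params": fit.exp_params,
                    "lin_params": fit.lin_params,
                    "r2_exp": fit.r2_exp,
                    "r2_lin": fit.r2_lin,
                },
                "binned_median_rank": {"distance": med_d, "rank": med_r},
                "coupling": coup,
                "connected_weight_spearman": geometry.connected_weight_correlation(m, sc),
            }
        report["stages"]["geometry"] = block
        report["timing_s"]["geometry"] = time.time() - t

    if config.stages.get("richclub", True):
        t = time.time()
        rp = config.richclub_params
        plain_nulls = rewire_preserving(
            sc, dist, n_bins=1, n_surrogates=rp["n_nulls"], seed=int(rng.integers(2**31))
        )
        k_max = min(rp["k_max"], int(sc.degree.max()))
        k_grid = range(rp["k_min"], k_max + 1)
        profile = richclub.rich_club_ratio(sc, k_grid, plain_nulls)
        sig_ks = profile.k_grid[profile.significant]
        k_star = int(sig_ks[len(sig_ks) // 2]) if sig_ks.size else int(np.median(list(k_grid)))
        rich_links = {
            m.mode_name: richclub.rich_link_rank(sc, tab, k_star)
            for m, tab in zip(modes, tables)
        }
        hub_vectors = {m.mode_name: richclub.hubness(tab) for m, tab in zip(modes, tables)}
        xmodal_hub = richclub.cross_modal_hubness(tables)
        intra = {}
        if parc.intrinsic_label is not None:
            for m in modes:
                pcts, fr = richclub.intra_class_fraction(m, parc.intrinsic_label)
                intra[m.mode_name] = {"pcts": pcts, "fraction": fr}
        report["stages"]["richclub"] = {
            "k_grid": profile.k_grid,
            "phi": profile.phi,
            "ratio": profile.ratio,
            "significant": profile.significant,
            "k_star": k_star,
            "rich_links": rich_links,
            "hubness": hub_vectors,
            "cross_modal_hubness": xmodal_hub,
            "intra_class_intrinsic": intra,
        }
        report["timing_s"]["richclub"] = time.time() - t

    if config.stages.get("exposure", True):
        t = time.time()
        ep = config.exposure_params
        ab_maps = [
            make_abnormality(
                modes[d % len(modes)], ep["abnormality_noise_sd"],
                seed=int(rng.integers(2**31)), disorder_name=f"disorder_{d}",
            )
            for d in range(ep["n_disorders"])
        ]
        panel = exposure_panel(modes, ab_maps, sc=sc, dist=dist)
        report["stages"]["exposure"] = {
            "panel": {row: panel.loc[row].to_dict() for row in panel.index},
        }
        report["timing_s"]["exposure"] = time.time() - t

    grads = None
    if config.stages.get("gradients", True):
        t = time.time()
        grads = [gradients.principal_gradients(m) for m in modes]
        corr, med_abs = gradients.gradient_correlations(grads)
        report["stages"]["gradients"] = {
            "var_explained": {
                m.mode_name: g.var_explained for m, g in zip(modes, grads)
            },
            "gradient_correlation": corr,
            "median_abs_gradient_r": med_abs,
        }
        report["timing_s"]["gradients"] = time.time() - t

    if config.stages.get("communities", True):
        t = time.time()
        cp = config.communities_params
        block = {}
        for m in modes:
            net = gradients.SignedNetwork.from_matrix(m)
            res = gradients.consensus_partition(
                net, cp["gamma"], n_reps=cp["n_reps"], seed=int(rng.integers(2**31))
            )
            entry = {
                "n_communities": res.n_communities,
                "Q": res.quality,
                "converged": res.converged,
            }
            if cp.get("sweep_gammas"):
                gg, nc = gradients.gamma_sweep(
                    net, np.asarray(cp["sweep_gammas"], dtype=float),
                    n_reps=cp["sweep_reps"], seed=int(rng.integers(2**31)),
                )
                entry["sweep"] = {"gamma": gg, "n_communities": nc}
            block[m.mode_name] = entry
        report["stages"]["communities"] = block
        report["timing_s"]["communities"] = time.time() - t

    fused = None
    if config.stages.get("fusion", True):
        t = time.time()
        fp = config.fusion_params
        fcfg = FusionConfig(mu=fp["mu"], K=fp["K"], n_iterations=fp["n_iterations"])
        fused = snf_fuse(modes, fcfg)
        from .core import ConnectivityMode

        fused_mode = ConnectivityMode(fused.matrix, mode_name="fused")
        if len(modes) >= 3:
            loo = leave_one_out_robustness(modes, fcfg)
        else:
            loo = {"per_mode": {}, "min": {"value": None, "reason": "needs >= 3 modes"}}
        entry = {
            "leave_one_out": loo,
            "fused_vs_structural_spearman": geometry.connected_weight_correlation(
                fused_mode, sc
            ),
            "fused_coupling": {
                k: v
                for k, v in geometry.structural_coupling_test(
                    fused_mode, sc, coupling_nulls
                ).items()
                if k != "null_deltas"
            },
            "nonnegative": bool(np.all(fused.matrix >= 0)),
        }
        if parc.intrinsic_label is not None and parc.cyto_label is not None:
            pcts, fr_both = richclub.intra_class_fraction(
                fused_mode, parc.intrinsic_label, combine=parc.cyto_label
            )
            _, fr_intr = richclub.intra_class_fraction(fused_mode, parc.intrinsic_label)
            entry["intra_class"] = {
                "pcts": pcts, "intrinsic": fr_intr, "intrinsic_and_cyto": fr_both,
            }
        if fp["sensitivity_k"] and fp["sensitivity_mu"]:
            grid = hyperparameter_sensitivity(
                modes, fp["sensitivity_k"], fp["sensitivity_mu"], fcfg
            )
            entry["hyperparameter_sensitivity"] = {
                "K": fp["sensitivity_k"], "mu": fp["sensitivity_mu"],
                "spearman": grid, "min": float(grid.min()),
            }
        report["stages"]["fusion"] = entry
        report["timing_s"]["fusion"] = time.time() - t

    if config.stages.get("spin", True) and grads is not None:
        t = time.time()
        perms = spin_permutations(
            parc, n_rotations=config.spin_params["n_rotations"],
            seed=int(rng.integers(2**31)),
        )
        xmodal = richclub.cross_modal_hubness(tables)
        sp = spin_correlation(xmodal, grads[0].scores[:, 0], perms)
        report["stages"]["spin"] = {
            "cross_modal_hubness_vs_first_gradient": {"r": sp["r"], "p_spin": sp["p_spin"]},
            "wall_hits": perms.wall_hits,
        }
        report["timing_s"]["spin"] = time.time() - t

    report["timing_s"]["total"] = time.time() - t0
    report = _clean(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in modes:
            save_matrix(m.matrix, out / f"{m.mode_name}.csv")
        save_matrix(sc.weights, out / "structural_connectome.csv")
        if fused is not None:
            save_matrix(fused.matrix, out / "fused.csv")
        save_centroids(parc.region_ids, parc.centroid_mm, out / "centroids_mm.csv")
        save_centroids(parc.region_ids, parc.centroid_sphere, out / "centroids_sphere.csv")
        save_labels(parc.region_ids, parc.hemisphere, out / "hemisphere.csv")
        save_labels(parc.region_ids, parc.intrinsic_label, out / "intrinsic.csv")
        save_labels(parc.region_ids, parc.cyto_label, out / "cyto.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
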