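"""End-to-end orchestration: morphometrics runs and simulation suites.

``run_morphometrics`` drives extract → featurize → normalise → cluster →
embed → categorise over a directory (or list) of label-mask images and
writes versioned CSV outputs plus a JSON run manifest.  ``run_simulation_suite``
runs the default vertex-model protocol next to its single-factor
perturbations (Rac inhibition, focal-adhesion reduction, tension change)
with paired seeds and writes per-condition time series and a summary table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import load_mask, save_trajectory
from .morphospace import build_morphospace, classify_aspect_ratio
from .shape_descriptors import DescriptorConfig, featurize
from .vertex_model import (
    CellSimulation,
    ModelParams,
    PhaseSchedule,
    default_params,
    default_schedule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_morphometrics",
    "run_simulation_suite",
    "STANDARD_CONDITIONS",
]


@dataclass
class RunConfig:
    """Configuration of one morphometrics run."""

    inputs: list[str]
    out_dir: str = "morphocell_run"
    pixel_size: float | None = None
    min_area: float = 20.0
    k: int = 3
    seed: int = 0
    n_restarts: int = 10
    thresholds: tuple[float, float] | None = None  # None = tertiles
    embed_method: str = "tsne"
    descriptor_options: dict = field(default_factory=dict)


def run_morphometrics(config: RunConfig) -> dict[str, Path]:
    """Execute the full shape-analysis pipeline and write its outputs.

    Returns the paths written: feature table, morphospace table, centroids,
    PCA loadings and the manifest.  Per-image failures are logged and
    skipped; an empty overall result raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = DescriptorConfig(min_area=config.min_area, **config.descriptor_options)

    tables = []
    for path in config.inputs:
        try:
            mask = load_mask(path, config.pixel_size)
            t = featurize(mask, cfg)
            t.insert(0, "image", Path(path).name)
            tables.append(t)
        except Exception as exc:
            logger.error("image %s failed: %s", path, exc)
    if not tables or all(t.empty for t in tables):
        raise RuntimeError("no cells measured in any input image")
    feats = pd.concat(tables, ignore_index=True)
    feats_ok = feats.dropna(subset=["roundness"]) if "error" in feats.columns else feats

    res = build_morphospace(
        feats_ok, k=config.k, seed=config.seed,
        n_restarts=config.n_restarts, embed_method=config.embed_method,
    )
    cats = classify_aspect_ratio(feats_ok, config.thresholds)

    enriched = feats_ok.copy().reset_index(drop=True)
    enriched["cluster"] = [f"T{c}" for c in res.cluster_labels]
    enriched["category"] = cats["category"].to_numpy()
    enriched["embed_x"] = res.embedding[:, 0]
    enriched["embed_y"] = res.embedding[:, 1]
    enriched["pc1"] = res.pca_scores[:, 0]
    enriched["pc2"] = res.pca_scores[:, 1]

    paths = {
        "features": out / "features.csv",
        "morphospace": out / "morphospace.csv",
        "centroids": out / "cluster_centroids.csv",
        "loadings": out / "pca_loadings.csv",
        "manifest": out / "manifest.json",
    }
    feats.to_csv(paths["features"], index=False, float_format="%.6g")
    enriched.to_csv(paths["morphospace"], index=False, float_format="%.6g")
    pd.DataFrame(
        res.cluster_centroids,
        columns=res.feature_columns,
        index=[f"T{i+1}" for i in range(config.k)],
    ).to_csv(paths["centroids"], float_format="%.6g")
    pd.DataFrame(
        res.pca_loadings,
        index=res.feature_columns,
        columns=[f"PC{i+1}" for i in range(res.pca_loadings.shape[1])],
    ).to_csv(paths["loadings"], float_format="%.6g")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "k": config.k,
        "n_restarts": config.n_restarts,
        "thresholds": list(cats[["threshold_low", "threshold_high"]].iloc[0]),
        "embed_method": config.embed_method,
        "pixel_size": config.pixel_size,
        "min_area": config.min_area,
        "inputs": [str(p) for p in config.inputs],
        "n_cells": int(len(enriched)),
        "explained_variance": [float(v) for v in res.explained_variance],
        "inertia": res.inertia,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


#: the single-factor perturbations of the three-phase protocol; scalings are
#: applied to the polarisation and depolarisation phases only (the first
#: phase has no Rac, fibres or adhesion to perturb)
STANDARD_CONDITIONS: dict[str, dict[str, float]] = {
    "default": {},
    "rac_inhibited": {"f_rac": 0.0},
    "fa_reduced": {"f_cams": 1.0},
    "weak_tension": {"k_tension_scale": 0.5},
}

#: width/length value below which the cell counts as clearly polarised
POLARITY_THRESHOLD = 0.75


def _apply_condition(schedule: PhaseSchedule, cond: dict[str, float]) -> PhaseSchedule:
    import copy

    sched = copy.deepcopy(schedule)
    for ph in sched.phases:
        if ph.name == "isotropic_expansion":
            continue
        for key, val in cond.items():
            if key.endswith("_scale"):
                base_key = key[: -len("_scale")]
                base = ph.overrides.get(base_key, getattr(default_params(), base_key))
                ph.overrides[base_key] = base * val
            else:
                ph.overrides[key] = val
    return sched


def run_simulation_suite(
    out_dir: str | Path,
    params: ModelParams | None = None,
    schedule: PhaseSchedule | None = None,
    conditions: dict[str, dict[str, float]] | None = None,
    seeds: list[int] | None = None,
    polarity_threshold: float = POLARITY_THRESHOLD,
) -> pd.DataFrame:
    """Run the perturbation-condition suite with paired seeds.

    Writes one morphometric time-series CSV per condition × seed plus a
    ``suite_summary.csv`` of per-run endpoints: phase-end circularities,
    minimum width/length ratio in the polarisation phase (peak polarity),
    time of first crossing of the polarity threshold, and final A-P length.
    Returns the summary table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or default_params()
    schedule = schedule or default_schedule()
    conditions = conditions if conditions is not None else STANDARD_CONDITIONS
    seeds = seeds if seeds is not None else [0]

    rows = []
    for cond_name, overrides in conditions.items():
        sched = _apply_condition(schedule, overrides)
        for seed in seeds:
            traj = CellSimulation(params, sched).run(seed=seed)
            save_trajectory(traj, out, stem=f"{cond_name}_seed{seed}")
            m = traj.metrics
            p2_lo, p2_hi = traj.phase_bounds.get(
                "ap_polarisation", (0.0, traj.times[-1])
            )
            p2 = m[(m.time > p2_lo) & (m.time <= p2_hi)]
            cross = m[(m.time > p2_lo) & (m.width_length_ratio < polarity_threshold)]
            pe = traj.phase_end_metrics()
            rows.append(
                {
                    "condition": cond_name,
                    "seed": seed,
                    "min_ratio_polarisation": float(p2.width_length_ratio.min()),
                    "t_polarity_crossing": (
                        float(cross.time.iloc[0]) if len(cross) else np.nan
                    ),
                    "final_ap_length": float(m.ap_length.iloc[-1]),
                    "final_ap_width": float(m.ap_width.iloc[-1]),
                    **{
                        f"circ_{name}": vals["circularity"]
                        for name, vals in pe.items()
                    },
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "suite_summary.csv", index=False, float_format="%.6g")
    return summary
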