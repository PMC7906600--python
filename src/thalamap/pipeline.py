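"""End-to-end orchestration: simulate → detect → dedup → assign → NND →
cluster → orient → stats, driven by one YAML/dict config.

Stages communicate only via the declared file formats written into the
output directory, so any stage can be re-run or tested in isolation.  The
report bundle (CSV/JSON outputs, resolved config, log) is a deterministic
function of the config and its seeds; the log carries no timestamps, so
re-running a bundle's resolved config reproduces it byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import clustering, detection, neighborhood, orientation, stats, synthetic
from .core import (
    RegionAtlas,
    assign_regions,
    counts_by_region,
    load_brain_datasets,
    save_cells,
)


class PipelineConfigError(ValueError):
    """Configuration invalid — raised before any computation starts."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


DEFAULT_STAGES = ("simulate", "detect", "dedup", "nnd", "cluster", "orient", "stats")


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Check every enabled stage has its input before any computation."""
    cfg = dict(config)
    stages = {s: bool(cfg.get("stages", {}).get(s, True)) for s in DEFAULT_STAGES}
    cells_cfg = cfg.get("cells", {})
    has_cells = bool(cells_cfg.get("path")) or "generate" in cells_cfg or stages["simulate"]
    for stage in ("detect", "dedup", "nnd", "cluster", "stats"):
        if stages[stage] and not has_cells:
            raise PipelineConfigError(
                f"stage {stage!r} enabled but no cell input or generator configured"
            )
    proc_cfg = cfg.get("processes", {})
    if stages["orient"] and not (
        proc_cfg.get("path") or "generate" in proc_cfg or stages["simulate"]
    ):
        raise PipelineConfigError(
            "stage 'orient' enabled but no process input or generator configured"
        )
    if "seed" not in cfg:
        raise PipelineConfigError("config must declare a seed")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all enabled stages; returns a manifest of written outputs."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: list[str] = [f"seed={seed}"]
    manifest: dict[str, str] = {}
    stages = {s: bool(cfg.get("stages", {}).get(s, True)) for s in DEFAULT_STAGES}

    atlas_path = cfg.get("atlas", "default")
    atlas = (
        synthetic.default_atlas()
        if atlas_path == "default"
        else RegionAtlas.from_json(atlas_path)
    )

    # --- simulate / load cells -------------------------------------------
    datasets = []
    try:
        cells_cfg = cfg.get("cells", {})
        if stages["simulate"] or "generate" in cells_cfg:
            gen = cells_cfg.get("generate", {})
            sim_cfg = synthetic.default_two_class_config(
                seed=seed,
                n_brains=int(gen.get("n_brains", 3)),
                n_cells_per_class=int(gen.get("n_cells_per_class", 1000)),
                sd_um=float(gen.get("sd_um", 150.0)),
                atlas=atlas,
            )
            datasets = synthetic.simulate_brains(sim_cfg)
            save_cells(datasets, out / "cells.csv")
            manifest["cells"] = "cells.csv"
            log.append(f"simulate: {len(datasets)} brains, "
                       f"{sum(len(d.cells) for d in datasets)} cells")
        elif cells_cfg.get("path"):
            datasets = load_brain_datasets(cells_cfg["path"])
            log.append(f"load cells: {len(datasets)} brains")
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("simulate", exc) from exc

    classes = cfg.get("nnd", {}).get("classes", ["classA", "classB"])

    # --- detect + dedup ---------------------------------------------------
    if stages["detect"] or stages["dedup"]:
        try:
            serial_cfg = synthetic.SerialImagingConfig(
                **cfg.get(
                    "serial",
                    {"optical_spacing_um": 10.0, "cell_radius_um": 10.0},
                )
            )
            all_events = []
            dedup_rows = []
            for i, ds in enumerate(datasets):
                events = synthetic.simulate_serial_detections(
                    ds.cells, serial_cfg, seed=seed + 1000 + i
                )
                all_events.extend(events)
                corrected = detection.correct_axial_oversampling(
                    events,
                    radius=float(cfg.get("dedup", {}).get("radius", 10.0)),
                    mode=cfg.get("dedup", {}).get("mode", "median"),
                )
                for p in corrected:
                    dedup_rows.append(
                        {"brain_id": ds.brain_id, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
                    )
                log.append(
                    f"dedup {ds.brain_id}: {len(events)} events -> "
                    f"{len(corrected)} cells (true {len(ds.cells)})"
                )
            detection.save_events(all_events, out / "events.csv")
            manifest["events"] = "events.csv"
            import pandas as pd

            pd.DataFrame(dedup_rows).to_csv(out / "dedup.csv", index=False)
            manifest["dedup"] = "dedup.csv"
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("dedup", exc) from exc

    # --- region counts ----------------------------------------------------
    try:
        import pandas as pd

        counts_frames = []
        for ds in datasets:
            ds.cells = assign_regions(ds.cells, atlas)
            tab = counts_by_region(ds)
            tab["brain_id"] = ds.brain_id
            counts_frames.append(tab.reset_index())
        if counts_frames:
            pd.concat(counts_frames).to_csv(out / "region_counts.csv", index=False)
            manifest["region_counts"] = "region_counts.csv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("assign", exc) from exc

    # --- NND --------------------------------------------------------------
    if stages["nnd"] and datasets:
        try:
            grid_size = int(cfg.get("nnd", {}).get("grid_size", 256))
            per_brain = [
                neighborhood.nnd_analysis(
                    ds.positions(classes[0]), ds.positions(classes[1]), ds.brain_id
                )
                for ds in datasets
            ]
            contrast = neighborhood.segregation_contrast(per_brain, grid_size)
            cdf_rows = {}
            for lab, summary in contrast["cdf"].items():
                cdf_rows[f"{lab}_mean"] = summary.mean
                cdf_rows[f"{lab}_sem"] = summary.sem
            import pandas as pd

            cdf_df = pd.DataFrame(
                {"grid": contrast["cdf"]["between"].grid, **cdf_rows}
            )
            cdf_df.to_csv(out / "nnd_cdf.csv", index=False)
            payload = {
                "ks_pooled": {
                    k: v.to_dict() for k, v in contrast["ks_pooled"].items()
                },
                "ks_per_brain": [
                    {
                        "brain_id": e["brain_id"],
                        "within-A_vs_between": e["within-A_vs_between"].to_dict(),
                        "within-B_vs_between": e["within-B_vs_between"].to_dict(),
                    }
                    for e in contrast["ks_per_brain"]
                ],
            }
            _write_json(out / "nnd.json", payload)
            manifest["nnd"] = "nnd.json"
            log.append(
                "nnd: pooled KS p (A vs between) = "
                f"{contrast['ks_pooled']['within-A_vs_between'].p_value:.3e}"
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("nnd", exc) from exc

    # --- clustering -------------------------------------------------------
    if stages["cluster"] and datasets:
        try:
            ccfg = cfg.get("cluster", {})
            k_range = range(int(ccfg.get("kmin", 2)), int(ccfg.get("kmax", 10)) + 1)
            n_init = int(ccfg.get("n_init", 10))
            per_brain_pts = [ds.positions() for ds in datasets]
            selection = clustering.select_k_multi(
                per_brain_pts, k_range=k_range, seed=seed, n_init=n_init
            )
            comps = []
            label_rows = []
            for ds, pts in zip(datasets, per_brain_pts):
                res = clustering.kmeans_fit(
                    pts, selection.chosen_k, seed=seed, n_init=n_init
                )
                comp = clustering.cluster_composition(res, ds.class_labels)
                comps.append(comp)
                for c, lab in zip(ds.cells, res.labels):
                    label_rows.append(
                        {"brain_id": ds.brain_id, "x_um": c.position.x,
                         "y_um": c.position.y, "z_um": c.position.z,
                         "class_label": c.class_label, "cluster": int(lab)}
                    )
            summary = clustering.capture_summary(comps)
            import pandas as pd

            pd.DataFrame(label_rows).to_csv(out / "cluster_labels.csv", index=False)
            payload = {
                "k_values": list(selection.k_values),
                "silhouette_mean": list(selection.silhouettes),
                "silhouette_sem": list(selection.silhouette_sems),
                "chosen_k": selection.chosen_k,
                "n_brains": selection.n_brains,
                "captures": summary.reset_index().to_dict(orient="records"),
            }
            _write_json(out / "clusters.json", payload)
            manifest["clusters"] = "clusters.json"
            log.append(f"cluster: chosen_k={selection.chosen_k}")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("cluster", exc) from exc

    # --- orientation ------------------------------------------------------
    if stages["orient"]:
        try:
            proc_cfg = cfg.get("processes", {})
            if proc_cfg.get("path"):
                records = orientation.load_processes(proc_cfg["path"])
            else:
                gen = proc_cfg.get("generate", {})
                direction = np.array(gen.get("mean_direction", [0.0, -1.0, 1.0]), float)
                direction = direction / np.linalg.norm(direction)
                mig = synthetic.MigrationConfig(
                    per_region={
                        str(gen.get("region", "LGd")): synthetic.RegionMigrationModel(
                            mean_direction=tuple(direction),
                            kappa=float(gen.get("kappa", 20.0)),
                            n_cells=int(gen.get("n_cells", 300)),
                        )
                    },
                )
                records = synthetic.simulate_migration(mig, atlas, seed=seed + 2000)
                orientation.save_processes(records, out / "processes.csv")
                manifest["processes"] = "processes.csv"
            fractions = orientation.dominant_axis_fractions(records)
            hist = orientation.angular_histogram(records)
            mean_dir, resultant = orientation.mean_resultant_direction(records)
            payload = {
                "n_records": len(records),
                "axis_fractions": dict(fractions.fractions),
                "zero_fractions": dict(fractions.zero_fractions),
                "mean_direction": mean_dir,
                "resultant_length": resultant,
                "theta_edges": hist.theta_edges,
                "phi_edges": hist.phi_edges,
                "frequencies": hist.frequencies,
            }
            _write_json(out / "orientation.json", payload)
            manifest["orientation"] = "orientation.json"
            log.append(f"orient: {len(records)} records, R={resultant:.3f}")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("orient", exc) from exc

    # --- stats ------------------------------------------------------------
    if stages["stats"] and datasets:
        try:
            import pandas as pd

            from functools import reduce

            tables = [counts_by_region(ds) for ds in datasets]
            total = (
                reduce(lambda a, b: a.add(b, fill_value=0), tables)
                .fillna(0)
                .astype(int)
            )
            # classes x regions: is the regional distribution homogeneous?
            table = total.T
            chi2 = stats.chi2_homogeneity(table)
            _write_json(out / "stats.json", {"chi2_class_by_region": chi2.to_dict()})
            manifest["stats"] = "stats.json"
            log.append(f"stats: chi2={chi2.statistic:.2f} p={chi2.p_value:.3e}")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("stats", exc) from exc

    _write_json(out / "resolved_config.json", cfg)
    manifest["resolved_config"] = "resolved_config.json"
    (out / "log.txt").write_text("\n".join(log) + "\n")
    manifest["log"] = "log.txt"
    return manifest
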