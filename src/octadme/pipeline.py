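"""Pipeline orchestration: simulate -> process -> metrics -> summarize -> tree.

A single :class:`PipelineConfig` (loadable from YAML/JSON) toggles the
stages and carries the per-stage parameter blocks; one global seed derives
per-stage sub-seeds.  Every run writes a provenance report (config echo,
seed, package version) alongside the data artifacts; artifacts themselves
carry no timestamps, so a repeated run with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import stage_seed
from .angiogram import (angiogram_filename, binarize, otsu_threshold,
                        read_angiogram, skeletonize, write_angiogram)
from .cohort import load_reference_cohort, read_cohort, write_cohort
from .lacunarity import LacunarityConfig, lacunarity, vascular_perfusion_density
from .simulate import (CohortSimParams, VesselSimParams, generate_angiogram,
                       generate_cohort)
from .stats import summarize_cohort, summary_report_markdown, summary_to_dict
from .tree import (TreeFitConfig, published_tree, r_squared, save_tree,
                   select_best_tree, tree_to_dict)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "octadme_run"
    rng_seed: int = 0
    # stage toggles
    simulate_cohort: bool = True
    simulate_angiograms: bool = False
    metrics: bool = False
    summarize: bool = True
    tree: bool = True
    use_reference_cohort: bool = False   # load packaged pseudo-cohort instead
    cohort_csv: str | None = None        # or an existing cohort table
    image_dir: str | None = None         # images for the metrics stage
    n_simulated_angiograms: int = 4      # eyes rendered when simulating images
    vessel_params: VesselSimParams = field(default_factory=VesselSimParams)
    cohort_params: CohortSimParams = field(default_factory=CohortSimParams)
    lacunarity_config: LacunarityConfig = field(default_factory=LacunarityConfig)
    tree_config: TreeFitConfig = field(default_factory=TreeFitConfig)
    published_leaf_overrides: dict[str, float] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        for name, sub_cls in (
            ("vessel_params", VesselSimParams),
            ("cohort_params", CohortSimParams),
            ("tree_config", TreeFitConfig),
        ):
            if name in raw:
                block = dict(raw.pop(name))
                for k in ("predictors", "max_depth_grid", "min_leaf_n_grid",
                          "cyst_radius_range"):
                    if k in block and isinstance(block[k], list):
                        block[k] = tuple(block[k])
                kwargs[name] = sub_cls(**block)
        if "lacunarity_config" in raw:
            block = dict(raw.pop("lacunarity_config"))
            if isinstance(block.get("box_sizes"), list):
                block["box_sizes"] = tuple(block["box_sizes"])
            kwargs["lacunarity_config"] = LacunarityConfig(**block)
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def image_metrics(
    image, config: LacunarityConfig | None = None
) -> dict:
    """Threshold, VPD and LAC of one angiogram (the per-image record)."""
    t = otsu_threshold(image)
    mask = binarize(image, t)
    skel = skeletonize(mask)
    fm = lacunarity(skel, config)
    return {
        "eye_id": image.eye_id,
        "plexus": image.plexus,
        "timepoint": image.timepoint,
        "threshold": t,
        "vpd": vascular_perfusion_density(mask),
        "lac": fm.lac,
        "lac_curve": {str(k): v for k, v in fm.lac_curve.items()},
    }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report dict.

    Writes under ``config.output_dir``: ``cohort.csv``, simulated PNGs,
    ``metrics.json``, ``summary.json``/``summary.md``, ``fitted_tree.json``,
    ``published_tree.json``, ``predictions.csv`` and ``run_report.json``.
    Any stage failure raises :class:`StageError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    table: pd.DataFrame | None = None
    # --- cohort acquisition ------------------------------------------------
    try:
        if config.use_reference_cohort:
            table = load_reference_cohort()
            report["stages"]["cohort"] = {"source": "packaged reference", "n": len(table)}
        elif config.cohort_csv:
            table = read_cohort(config.cohort_csv)
            report["stages"]["cohort"] = {"source": config.cohort_csv, "n": len(table)}
        elif config.simulate_cohort:
            params = dataclasses.replace(
                config.cohort_params,
                rng_seed=stage_seed(config.rng_seed, "simulate_cohort"),
            )
            table = generate_cohort(params)
            report["stages"]["cohort"] = {"source": "simulated", "n": len(table)}
        if table is not None:
            write_cohort(table, out / "cohort.csv")
    except Exception as exc:
        raise StageError(f"cohort stage failed: {exc}") from exc

    # --- angiogram simulation ---------------------------------------------
    if config.simulate_angiograms:
        try:
            img_dir = out / "angiograms"
            img_dir.mkdir(exist_ok=True)
            n_img = config.n_simulated_angiograms
            written = []
            for i in range(n_img):
                for plexus in ("scp", "dcp"):
                    params = dataclasses.replace(
                        config.vessel_params,
                        rng_seed=stage_seed(config.rng_seed, f"angio_{plexus}", i),
                    )
                    eye_id = (table["eye_id"].iloc[i] if table is not None
                              and i < len(table) else f"SIM{i:05d}")
                    img = generate_angiogram(params, plexus=plexus, eye_id=eye_id)
                    fname = angiogram_filename(eye_id, plexus, "baseline")
                    write_angiogram(img, img_dir / fname)
                    written.append(fname)
            report["stages"]["simulate_angiograms"] = {"n_images": len(written)}
            if config.image_dir is None:
                config.image_dir = str(img_dir)
        except Exception as exc:
            raise StageError(f"simulate_angiograms stage failed: {exc}") from exc

    # --- image metrics -----------------------------------------------------
    if config.metrics:
        try:
            if not config.image_dir:
                raise ValueError("metrics stage enabled but no image_dir")
            rows = []
            for path in sorted(Path(config.image_dir).glob("*.png")):
                eye_id, plexus, timepoint = path.stem.rsplit("_", 2)
                img = read_angiogram(path, plexus=plexus.lower(), eye_id=eye_id,
                                     timepoint=timepoint)
                rows.append(image_metrics(img, config.lacunarity_config))
            (out / "metrics.json").write_text(json.dumps(rows, indent=2) + "\n")
            # merge baseline metrics into the cohort table columns
            if table is not None:
                for row in rows:
                    if row["timepoint"] != "baseline":
                        continue
                    sel = table["eye_id"] == row["eye_id"]
                    table.loc[sel, f"vpd_{row['plexus']}"] = row["vpd"]
                    table.loc[sel, f"lac_{row['plexus']}"] = row["lac"]
                write_cohort(table, out / "cohort.csv")
            report["stages"]["metrics"] = {"n_images": len(rows)}
        except Exception as exc:
            raise StageError(f"metrics stage failed: {exc}") from exc

    # --- summary -----------------------------------------------------------
    if config.summarize:
        try:
            if table is None:
                raise ValueError("summarize stage enabled but no cohort available")
            summary = summarize_cohort(table)
            (out / "summary.json").write_text(
                json.dumps(summary_to_dict(summary), indent=2, default=float) + "\n"
            )
            (out / "summary.md").write_text(summary_report_markdown(summary))
            report["stages"]["summarize"] = {
                "n_continuous": len(summary.continuous),
                "n_flags": len(summary.flags),
            }
        except Exception as exc:
            raise StageError(f"summarize stage failed: {exc}") from exc

    # --- tree --------------------------------------------------------------
    if config.tree:
        try:
            if table is None:
                raise ValueError("tree stage enabled but no cohort available")
            fitted, r2 = select_best_tree(table, config.tree_config)
            save_tree(fitted, out / "fitted_tree.json")
            pub = published_tree(config.published_leaf_overrides or None)
            save_tree(pub, out / "published_tree.json")
            preds = table.copy()
            preds["bcva_final_pred"] = fitted.predict_table(table)
            write_cohort(preds[["eye_id", "bcva_final_pred"]], out / "predictions.csv")
            report["stages"]["tree"] = {
                "r_squared": r2,
                "n_leaves": fitted.root.n_leaves(),
                "depth": fitted.root.depth(),
            }
        except Exception as exc:
            raise StageError(f"tree stage failed: {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def parameter_recovery_experiment(
    cohort_params: CohortSimParams | None = None,
    tree_config: TreeFitConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
) -> dict:
    """Simulate cohorts, refit trees, and score recovery of the generating rule.

    Per replicate: simulate a cohort -> select the best tree on the grid ->
    record (a) the fraction of rows whose fitted prediction is nearest the
    true branch's leaf value (routing agreement), (b) the fitted CMT and
    DCP-LAC thresholds nearest the generating splits, and (c) the training
    r^2.  Returns per-replicate records plus median/quantile aggregates.
    """
    from .simulate import BRANCHES, CMT_SPLIT, LAC_SPLIT

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cohort_params = cohort_params or CohortSimParams()
    tree_config = tree_config or TreeFitConfig()
    records = []
    failures = []
    for rep in range(n_replicates):
        sub = stage_seed(seed, "recovery", rep)
        try:
            params = dataclasses.replace(cohort_params, rng_seed=sub)
            table = generate_cohort(params)
            fitted, r2 = select_best_tree(table, tree_config)
            preds = fitted.predict_table(table)
            leaf_vals = np.array([
                cohort_params.leaf_values[b] for b in BRANCHES
            ], dtype=float)
            true_vals = np.array([
                cohort_params.leaf_values[b] for b in table["true_branch"]
            ], dtype=float)
            nearest = leaf_vals[np.argmin(
                np.abs(preds[:, None] - leaf_vals[None, :]), axis=1)]
            agreement = float(np.mean(nearest == true_vals))
            thresholds = _collect_thresholds(fitted.root)
            rec = {
                "replicate": rep,
                "seed": sub,
                "routing_agreement": agreement,
                "r_squared": r2,
                "cmt_threshold": _nearest(thresholds.get("cmt_baseline", []), CMT_SPLIT),
                "lac_threshold": _nearest(thresholds.get("lac_dcp", []), LAC_SPLIT),
            }
            records.append(rec)
        except Exception as exc:  # propagate per replicate
            failures.append({"replicate": rep, "error": str(exc)})
    if not records:
        raise RuntimeError(f"all {n_replicates} replicates failed: {failures}")
    agg = {}
    for key in ("routing_agreement", "r_squared", "cmt_threshold", "lac_threshold"):
        vals = np.array([r[key] for r in records if r[key] is not None], dtype=float)
        if vals.size:
            agg[key] = {
                "median": float(np.median(vals)),
                "q25": float(np.quantile(vals, 0.25)),
                "q75": float(np.quantile(vals, 0.75)),
            }
    return {"replicates": records, "failures": failures, "aggregate": agg}


def _collect_thresholds(node, acc: dict[str, list] | None = None) -> dict[str, list]:
    acc = {} if acc is None else acc
    if not node.is_leaf:
        acc.setdefault(node.split_var, []).append(node.threshold)
        _collect_thresholds(node.low, acc)
        _collect_thresholds(node.high, acc)
    return acc


def _nearest(values: list[float], target: float) -> float | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return float(arr[np.argmin(np.abs(arr - target))])
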