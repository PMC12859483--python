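"""Compose the modules into the full configuration-driven workflow:

read -> filter -> (QC + normalize) -> log2 -> model scan ->
component-to-class ladder -> classify -> uncertainty -> summaries -> maps,

with structured logging and a reproducible run manifest.  The manifest stores
the fully resolved config, its hash, the seed and library versions, and is
sufficient to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy
import sklearn

import ploidymapper
from ploidymapper import feature_io, preprocess
from ploidymapper.feature_io import FeatureTable
from ploidymapper.mixture import FitParams, model_scan, model_to_json, posteriors
from ploidymapper.ploidy_assign import (
    classify,
    map_components_to_classes,
    uncertainty_intervals,
)
from ploidymapper.ploidy_map import render_ploidy_map
from ploidymapper.summarize import class_means_and_folds, class_proportions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class _EventLog:
    def __init__(self) -> None:
        self.events: list[dict] = []

    def log(self, stage: str, level: str, message: str) -> None:
        self.events.append({"stage": stage, "level": level, "message": message})
        getattr(logger, level, logger.info)("[%s] %s", stage, message)


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _apply_filters(
    table: FeatureTable, filter_specs: list[dict], events: _EventLog
) -> FeatureTable:
    for spec in filter_specs:
        op = spec.get("op")
        before = len(table)
        if op == "select_by_label":
            table = preprocess.select_by_label(
                table,
                exclude=spec.get("exclude", ()),
                include=spec.get("include"),
            )
        elif op == "threshold":
            table = preprocess.threshold_filter(
                table,
                feature=spec["feature"],
                cutoff=float(spec["cutoff"]),
                keep=spec.get("keep", "above"),
            )
        else:
            raise PipelineError("filter", f"unknown filter op {op!r}")
        events.log(
            "filter", "info",
            f"{op}: kept {len(table)} of {before} records",
        )
    return table


def run_pipeline(config: dict, base_dir: Optional[str | Path] = None) -> dict:
    """Execute the full workflow described by ``config``; return the manifest.

    Raises :class:`PipelineError` with a stage tag on failure (unreadable
    input, QC gate failure for a normalization-requiring recipe, empty
    post-filter table, ...).
    """
    config = copy.deepcopy(config)
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    events = _EventLog()
    seed = int(config.get("seed", 0))

    # --- read ------------------------------------------------------------
    input_block = config.get("input", {})
    table_path = input_block.get("feature_table")
    if not table_path:
        raise PipelineError("read", "config.input.feature_table is required")
    table_path = Path(table_path)
    if not table_path.is_absolute():
        table_path = base_dir / table_path
    try:
        table = feature_io.read_feature_table(
            table_path, dialect=input_block.get("dialect")
        )
    except feature_io.FeatureIOError as exc:
        raise PipelineError("read", str(exc)) from exc
    events.log("read", "info", f"read {len(table)} records from {table_path}")
    if len(table) == 0:
        raise PipelineError("read", f"feature table {table_path} has no records")

    label_image = None
    if input_block.get("label_image"):
        label_path = Path(input_block["label_image"])
        if not label_path.is_absolute():
            label_path = base_dir / label_path
        try:
            label_image = feature_io.read_label_image(label_path)
        except feature_io.FeatureIOError as exc:
            raise PipelineError("read", str(exc)) from exc
        events.log("read", "info", f"read label image {label_path}")

    # --- normalize (optional) -------------------------------------------
    norm = config.get("normalization")
    if norm:
        ref_label = norm.get("reference_label", "spermatid")
        ref_values = [
            rec.total_intensity
            for rec in table.records
            if rec.user_label == ref_label
        ]
        report = preprocess.reference_qc(
            ref_values,
            min_n=int(norm.get("min_n", 10)),
            median_range=tuple(norm.get("median_range", (2000.0, 6000.0))),
            band=tuple(norm.get("band", (0.5, 1.5))),
            min_fraction=float(norm.get("min_fraction", 0.9)),
        )
        events.log(
            "normalize", "info",
            f"reference QC: n={report.n_reference}, "
            f"median={report.median_intensity:g}, "
            f"fraction_in_band={report.fraction_in_band:.3f}, "
            f"passed={report.passed}",
        )
        if not report.passed:
            raise PipelineError(
                "normalize",
                f"reference QC failed ({', '.join(report.reasons)}); "
                f"experiment not considered",
            )
        table = preprocess.select_by_label(table, exclude={ref_label})
        table = preprocess.normalize_by_reference(
            table, report.median_intensity
        )

    # --- filter ----------------------------------------------------------
    table = _apply_filters(table, config.get("filters", []), events)
    if len(table) == 0:
        raise PipelineError("filter", "no records left after filtering")

    # --- features --------------------------------------------------------
    features = config.get("features", ["total_intensity"])
    try:
        X, survivors = preprocess.log2_features(table, features)
    except ValueError as exc:
        raise PipelineError("features", str(exc)) from exc
    events.log(
        "features", "info",
        f"log2 matrix {X.shape[0]} x {X.shape[1]} over {features}",
    )

    # --- fit -------------------------------------------------------------
    mix = config.get("mixture", {})
    k_lo, k_hi = mix.get("k_range", [1, 6])
    families = mix.get("families", ["spherical"])
    param_overrides = dict(mix.get("params", {}))
    param_overrides.setdefault("seed", seed)
    params = FitParams.defaults_for(X.shape[1], **param_overrides)
    scan = model_scan(
        X, range(int(k_lo), int(k_hi) + 1), families, params,
        feature_names=features,
    )
    for warning in scan.warnings:
        events.log("fit", "warning", warning)
    criterion = mix.get("criterion", "bic")
    best = scan.best(criterion)
    events.log(
        "fit", "info",
        f"selected K={best.K}, family={best.family} by {criterion} "
        f"(AIC best {scan.best_by_aic}, BIC best {scan.best_by_bic})",
    )

    # --- classify --------------------------------------------------------
    ladder_cfg = config.get("ladder", {})
    class_map = map_components_to_classes(
        best,
        base_class=ladder_cfg.get("base_class", "2C"),
        drop_lowest=bool(ladder_cfg.get("drop_lowest", False)),
        open_top=bool(ladder_cfg.get("open_top", False)),
        anchor_feature=ladder_cfg.get("anchor_feature"),
    )
    P = posteriors(best, X)
    unc = config.get("uncertainty", {})
    conf = float(unc.get("confident", 0.8))
    second = float(unc.get("second", 0.2))
    assignment = classify(P, class_map, conf, second)
    summary = uncertainty_intervals(assignment, conf, second)
    events.log(
        "classify", "info",
        f"classified {assignment.n_classified} of {len(assignment)} nuclei "
        f"into {class_map.ladder}",
    )

    # --- summarize -------------------------------------------------------
    groups = [table.records[int(i)].group for i in survivors]
    proportions = class_proportions(assignment, groups)
    stats = class_means_and_folds(table, assignment, features, index_map=survivors)

    # --- write -----------------------------------------------------------
    output_dir = Path(config.get("output_dir", "ploidymapper_run"))
    if not output_dir.is_absolute():
        output_dir = base_dir / output_dir
    output_dir.mkdir(parents=True, exist_ok=True)

    assignments_path = output_dir / "assignments.csv"
    feature_io.write_assignments(table, assignment, assignments_path, survivors)
    model_path = output_dir / "model.json"
    model_path.write_text(json.dumps(model_to_json(best), indent=2))

    summary_doc = {
        "classes": summary.classes,
        "class_summary": summary.to_dict(),
        "proportions_by_group": proportions.to_dict(),
        "class_stats": stats.to_dict(),
        "model": {
            "K": best.K,
            "family": best.family,
            "criterion": criterion,
            "aic": best.aic,
            "bic": best.bic,
            "log_likelihood": best.log_likelihood,
            "n": best.n,
            "d": best.d,
            "best_by_aic": list(scan.best_by_aic),
            "best_by_bic": list(scan.best_by_bic),
            "monotonic_aic": scan.monotonic_aic,
            "monotonic_bic": scan.monotonic_bic,
        },
        "warnings": scan.warnings,
        "seed": seed,
    }
    summary_path = output_dir / "summary.json"
    summary_path.write_text(json.dumps(summary_doc, indent=2))

    artifacts = {
        "assignments": str(assignments_path),
        "model": str(model_path),
        "summary": str(summary_path),
    }
    if label_image is not None:
        object_ids = [table.records[int(i)].object_id for i in survivors]
        map_image = render_ploidy_map(
            label_image, assignment, object_ids,
            palette=config.get("map", {}).get("palette"),
        )
        artifacts.update(map_image.save(output_dir))
        events.log("map", "info", "rendered ploidy map")

    manifest = {
        "config": config,
        "config_sha256": _config_hash(config),
        "seed": seed,
        "versions": {
            "ploidymapper": ploidymapper.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "events": events.events,
        "artifacts": artifacts,
    }
    manifest_path = output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def run_from_manifest(path: str | Path, base_dir: Optional[str | Path] = None) -> dict:
    """Re-run a pipeline from a previously written manifest."""
    manifest = json.loads(Path(path).read_text())
    return run_pipeline(manifest["config"], base_dir=base_dir)
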