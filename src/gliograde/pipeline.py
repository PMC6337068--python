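"""End-to-end orchestration: simulate -> ROI/segment/features -> select ->
train -> explain -> report, with a YAML config, per-stage artifacts and a run
manifest of checksums for reproducibility audits."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gliograde import explain as explain_mod
from gliograde import features as features_mod
from gliograde import grading, selection, synthetic
from gliograde.errors import ConfigurationError, StageError
from gliograde.roi import DEFAULT_ROI_K
from gliograde.segmentation import SegmentationParams

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "out_dir", "master_seed", "counts_by_grade", "tile_size_px", "tiles_per_side",
    "write_images", "roi_k", "segmentation", "subvisual_stage_targets",
    "visual_target", "selection_forest_size", "selection_cv_folds",
    "train_fraction", "n_repeats", "model_families", "model_grids",
    "explain_n_samples", "explain_top_k", "explain_cases_per_grade",
}
_REQUIRED_KEYS = {"out_dir", "master_seed"}
_SEG_KEYS = {"threshold_method", "fixed_threshold", "min_nucleus_area_px",
             "seed_min_distance_px", "opening_radius_px"}


@dataclass
class PipelineConfig:
    out_dir: str = "gliograde_run"
    master_seed: int = 0
    counts_by_grade: dict = field(default_factory=lambda: {"II": 49, "III": 45, "IV": 52})
    tile_size_px: int = 512                  # 5120 for real-slide mode
    tiles_per_side: int = 1
    write_images: bool = False
    roi_k: int = DEFAULT_ROI_K
    segmentation: dict = field(default_factory=dict)
    subvisual_stage_targets: tuple = tuple(selection.SUBVISUAL_STAGE_TARGETS)
    visual_target: int = selection.VISUAL_TARGET
    selection_forest_size: int = selection.DEFAULT_FOREST_SIZE
    selection_cv_folds: int = 5
    train_fraction: float = grading.DEFAULT_TRAIN_FRACTION
    n_repeats: int = grading.DEFAULT_N_REPEATS
    model_families: tuple = ("RF", "GBDT", "SVM", "NN")
    model_grids: dict = field(default_factory=dict)   # family -> grid override
    explain_n_samples: int = explain_mod.DEFAULT_N_SAMPLES
    explain_top_k: int = explain_mod.DEFAULT_TOP_K
    explain_cases_per_grade: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        missing = _REQUIRED_KEYS - set(raw)
        if missing:
            raise ConfigurationError(f"missing required config key(s): {sorted(missing)}")
        seg_unknown = set(raw.get("segmentation", {})) - _SEG_KEYS
        if seg_unknown:
            raise ConfigurationError(f"unknown segmentation key(s): {sorted(seg_unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        self.cohort_config().validate()
        self.segmentation_params().validate()
        if self.roi_k < 1:
            raise ConfigurationError("roi_k must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        known = {"RF", "GBDT", "SVM", "NN"}
        bad = set(self.model_families) - known
        if bad:
            raise ConfigurationError(f"unknown model family {sorted(bad)}; expected {sorted(known)}")

    def cohort_config(self) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(
            counts_by_grade=dict(self.counts_by_grade),
            tile_size_px=self.tile_size_px,
            tiles_per_side=self.tiles_per_side,
        )

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def model_specs(self) -> list[grading.ModelSpec]:
        specs = [s for s in grading.default_model_specs() if s.family in self.model_families]
        for s in specs:
            if s.family in self.model_grids:
                s.grid = dict(self.model_grids[s.family])
        return specs

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full workflow; returns the run manifest (also written to disk).

    With ``resume=True`` the feature stage reloads ``features.csv`` if it
    already exists under the (config-hash keyed) output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.master_seed,
                      "package_version": __import__("gliograde").__version__,
                      "stages": {}, "checksums": {}}

    def stage_done(name):
        manifest["stages"][name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # --- simulate ---------------------------------------------------------
    try:
        cohort = synthetic.generate_cohort(
            config.cohort_config(), config.master_seed,
            out_dir=out / "cohort" if config.write_images else None)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    stage_done("simulate")

    # --- roi + segment + features ----------------------------------------
    features_csv = out / "features.csv"
    cache_ok = resume and features_csv.exists()
    if cache_ok:
        table = pd.read_csv(features_csv)
        logger.info("resumed feature table from %s", features_csv)
    else:
        table = features_mod.build_feature_table(
            cohort, seg_params=config.segmentation_params(),
            tile_size_px=config.tile_size_px, roi_k=config.roi_k)
        if table.empty:
            raise StageError("features", "no case produced a feature row",
                             [c for c, _ in table.attrs.get("skipped", [])])
        table.to_csv(features_csv, index=False, float_format="%.12g")
        with open(out / "feature_ledger.json", "w") as fh:
            json.dump(features_mod.feature_ledger(), fh, indent=1)
        if table.attrs.get("skipped"):
            with open(out / "skipped_cases.json", "w") as fh:
                json.dump(table.attrs["skipped"], fh, indent=1)
    stage_done("features")

    # --- select -----------------------------------------------------------
    try:
        sel = selection.select_paper_battery(
            table, seed=config.master_seed,
            subvisual_stage_targets=tuple(config.subvisual_stage_targets),
            visual_target=config.visual_target,
            forest_size=config.selection_forest_size,
            cv_folds=config.selection_cv_folds)
    except Exception as exc:
        raise StageError("select", str(exc)) from exc
    sel["model_table"].to_csv(out / "selected_features.csv", index=False,
                              float_format="%.12g")
    with open(out / "selection.json", "w") as fh:
        json.dump({k: sel[k] for k in ("visual_selected", "subvisual_selected",
                                       "visual_trace", "subvisual_trace")}, fh, indent=1)
    stage_done("select")

    # --- train ------------------------------------------------------------
    scheme = grading.SplitScheme(config.train_fraction, config.n_repeats,
                                 master_seed=config.master_seed)
    try:
        metrics = grading.evaluate(config.model_specs(), sel["model_table"], scheme,
                                   feature_columns=sel["model_columns"])
    except Exception as exc:
        raise StageError("train", str(exc)) from exc
    for family, m in metrics.items():
        np.savetxt(out / f"confusion_{family}.csv", m.confusion, fmt="%d", delimiter=",",
                   header=",".join(m.classes), comments="")
        m.prediction_log.to_csv(out / f"predictions_{family}.csv", index=False)
    stage_done("train")

    # --- explain ----------------------------------------------------------
    best_family = max(metrics, key=lambda f: metrics[f].aggregate["accuracy"][0])
    spec = [s for s in config.model_specs() if s.family == best_family][0]
    mt = sel["model_table"]
    fitted = grading.tune_and_train(spec, mt[sel["model_columns"]], mt["grade"],
                                    seed=config.master_seed)
    explanations = {}
    for grade in synthetic.GRADES:
        ids = mt.loc[mt["grade"] == grade, "case_id"].tolist()
        for cid in ids[: config.explain_cases_per_grade]:
            reports = explain_mod.explain_case(
                cid, fitted, mt, sel["model_columns"],
                n_samples=config.explain_n_samples, top_k=config.explain_top_k,
                seed=config.master_seed)
            explanations[cid] = {
                cls: {"contributions": r.contributions, "intercept": r.intercept,
                      "weighted_r2": r.weighted_r2,
                      "predicted_proba": r.predicted_proba}
                for cls, r in reports.items()
            }
    with open(out / "explanations.json", "w") as fh:
        json.dump(explanations, fh, indent=1)
    stage_done("explain")

    # --- report -----------------------------------------------------------
    write_report(metrics, sel, explanations, out, best_family=best_family)
    stage_done("report")

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        manifest["checksums"][f.name] = _sha256(f)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def write_report(metrics: dict, sel: dict, explanations: dict,
                 out_dir: str | Path, best_family: str | None = None) -> None:
    """Model-comparison table, per-grade accuracies, confusion matrices and
    case explanations as one JSON plus a human-readable Markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model_rows = {}
    for family, m in metrics.items():
        model_rows[family] = {
            metric: {"mean": mu, "sd": sd}
            for metric, (mu, sd) in m.aggregate.items()
        }
    report = {
        "models": model_rows,
        "best_family": best_family,
        "per_grade_accuracy": {f: m.per_grade_accuracy for f, m in metrics.items()},
        "confusion_matrices": {f: {"classes": list(m.classes),
                                   "matrix": m.confusion.tolist()}
                               for f, m in metrics.items()},
        "selected_features": {"visual": sel["visual_selected"],
                              "subvisual": sel["subvisual_selected"]},
        "explanations": explanations,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    def pm(family, metric):
        mu, sd = metrics[family].aggregate[metric]
        return f"{mu:.2f} ± {sd:.2f}"

    lines = ["# Grading run report", "", "## Model comparison (mean ± SD over repeats)", "",
             "| Model | F1 (macro) | Accuracy | Precision (macro) | Recall (macro) |",
             "|-------|-----------|----------|-------------------|----------------|"]
    for family in metrics:
        lines.append(f"| {family} | {pm(family, 'f1_macro')} | {pm(family, 'accuracy')} | "
                     f"{pm(family, 'precision_macro')} | {pm(family, 'recall_macro')} |")
    lines += ["", "## Per-grade accuracy (pooled class recall)", ""]
    for family, m in metrics.items():
        acc = ", ".join(f"{g}: {v:.2f}" if v is not None else f"{g}: n/a"
                        for g, v in m.per_grade_accuracy.items())
        lines.append(f"- {family}: {acc}")
    lines += ["", "## Pooled confusion matrices (rows = true grade)", ""]
    for family, m in metrics.items():
        lines += [f"### {family}", "", "| true\\pred | " + " | ".join(m.classes) + " |",
                  "|" + "---|" * (len(m.classes) + 1)]
        for i, g in enumerate(m.classes):
            lines.append(f"| {g} | " + " | ".join(str(int(v)) for v in m.confusion[i]) + " |")
        lines.append("")
    lines += ["## Selected features", "",
              f"- visual ({len(sel['visual_selected'])}): "
              + ", ".join(sel["visual_selected"]),
              f"- sub-visual ({len(sel['subvisual_selected'])}): "
              + ", ".join(sel["subvisual_selected"]),
              "- IHC: ki67_pi (always retained)", ""]
    if explanations:
        lines += ["## Case explanations (top contributions to the true-class probability)", ""]
        for cid, per_class in explanations.items():
            lines.append(f"### {cid}")
            for cls, rep in per_class.items():
                top = list(rep["contributions"].items())[:3]
                tops = ", ".join(f"{n}: {v:+.3f}" for n, v in top)
                lines.append(f"- grade {cls} (p={rep['predicted_proba'].get(cls, 0):.2f}): {tops}")
            lines.append("")
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(lines))
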