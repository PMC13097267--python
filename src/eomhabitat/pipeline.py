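"""End-to-end orchestration: thresholds -> habitat maps -> features -> statistics.

Each stage leaves its artifact on disk (thresholds.json, per-patient label
maps, features.csv, stats_report.json, roc_report.csv) together with a
metadata sidecar carrying the configuration hash, so outputs from different
configurations cannot be silently mixed. Re-running with identical inputs
and configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FEATURE_COLUMNS, cohort_feature_table, load_patient_images, patient_features
from .habitat import ThresholdPair, compute_cohort_thresholds, segment_patient, write_labelmap
from .io import CohortManifest, read_manifest
from .stats import compare_feature, evaluate_response_markers

__all__ = ["RunConfig", "run_all", "stats_report"]

log = logging.getLogger("eomhabitat")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; hashable for artifact provenance."""

    bins: int = 256
    pooling: str = "cohort_all_timepoints"
    seed: int = 0
    marker_features: tuple[str, ...] = ("dvol_LH", "dpct_volume_whole")
    write_labelmaps: bool = True

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.pooling not in ("cohort_all_timepoints", "per_timepoint"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        unknown = [f for f in self.marker_features if f not in FEATURE_COLUMNS]
        if unknown:
            raise ValueError(f"unknown marker feature(s): {unknown}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "marker_features" in d:
            d["marker_features"] = tuple(d["marker_features"])
        return cls(**d)


def _write_meta(out_dir: Path, name: str, config: RunConfig, extra: dict | None = None) -> None:
    meta = {"artifact": name, "config_hash": config.hash(), "config": asdict(config), "version": __version__}
    if extra:
        meta.update(extra)
    (out_dir / f"{name}.meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def check_meta(path: str | Path, config: RunConfig) -> None:
    """Refuse to consume an artifact produced under a different configuration."""
    meta_path = Path(path)
    if not meta_path.exists():
        return  # externally produced input: nothing to check
    meta = json.loads(meta_path.read_text())
    if meta.get("config_hash") != config.hash():
        raise RuntimeError(
            f"configuration mismatch: {meta_path} was produced under config hash "
            f"{meta.get('config_hash')}, current config hash is {config.hash()}"
        )


def stats_report(features: pd.DataFrame, config: RunConfig) -> dict:
    """Group comparisons for every habitat feature plus the marker ROC table."""
    comparisons = []
    for feat in FEATURE_COLUMNS:
        try:
            res = compare_feature(features, feat)
        except ValueError as exc:
            comparisons.append({"feature": feat, "error": str(exc)})
            continue
        comparisons.append(
            {
                "feature": feat,
                "test": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "groups": {k: dict(v) for k, v in res.group_summaries.items()},
            }
        )
    roc_table, note = marker_roc_table(features, config)
    report = {"group_comparisons": comparisons, "roc_table": roc_table.to_dict(orient="records")}
    if note:
        report["note"] = note
    return report


def marker_roc_table(features: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, str | None]:
    """Marker ROC table; on cohorts too small for the logistic combination,
    falls back to single-feature rows with an explanatory note."""
    try:
        return evaluate_response_markers(features, config.marker_features), None
    except ValueError as exc:
        from .stats import _roc_row, roc_analysis

        complete = features[list(config.marker_features) + ["response"]].dropna()
        table = pd.DataFrame(
            [
                _roc_row(f, roc_analysis(complete[f], complete["response"]), show_cutoff=True)
                for f in config.marker_features
            ]
        )
        return table, f"combined model not fitted: {exc}"


def run_all(manifest_path: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> Path:
    """Run every stage on a cohort manifest; returns the run directory.

    Writes: thresholds.json, habitats/<patient>_<tp>_habitat.nii.gz (+ JSON
    label dictionaries), features.csv, stats_report.json, roc_report.csv and
    run.log. Any per-patient failure aborts the run naming the patient.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("eomhabitat %s | config_hash=%s | config=%s", __version__, config.hash(), asdict(config))
        manifest = read_manifest(manifest_path)
        log.info("manifest: %d patients from %s", len(manifest), manifest_path)

        cohort_images = []
        for pid, response, paths in manifest.patients():
            try:
                cohort_images.append((pid, response, load_patient_images(paths)))
            except Exception as exc:
                raise RuntimeError(f"stage=load patient={pid}: {exc}") from exc

        thresholds = compute_cohort_thresholds(
            [imgs for _, _, imgs in cohort_images], bins=config.bins, pooling=config.pooling
        )
        tp_json = out_dir / "thresholds.json"
        if isinstance(thresholds, dict):
            payload = {tp: {"t_water": t.t_water, "t_fat": t.t_fat} for tp, t in thresholds.items()}
            tp_json.write_text(json.dumps(payload, indent=2, sort_keys=True))
        else:
            thresholds.to_json(tp_json)
        _write_meta(out_dir, "thresholds", config)
        log.info("thresholds: %s", tp_json.read_text().replace("\n", " "))

        rows = []
        habitat_dir = out_dir / "habitats"
        if config.write_labelmaps:
            habitat_dir.mkdir(exist_ok=True)
        for pid, response, images in cohort_images:
            try:
                feats = patient_features(images, thresholds)
                if config.write_labelmaps:
                    for tp in ("pre", "post"):
                        t = thresholds[tp] if isinstance(thresholds, dict) else thresholds
                        labels = segment_patient(
                            images[f"{tp}_water"], images[f"{tp}_fat"], images[f"mask_{tp}"], t
                        )
                        write_labelmap(labels, habitat_dir / f"{pid}_{tp}_habitat.nii.gz")
                        log.info("patient=%s tp=%s habitat_counts=%s", pid, tp, labels.counts())
            except Exception as exc:
                raise RuntimeError(f"stage=features patient={pid}: {exc}") from exc
            row = {"patient_id": pid, "response": response}
            row.update(feats.as_row())
            rows.append(row)
        features = pd.DataFrame(rows, columns=["patient_id", "response", *FEATURE_COLUMNS])
        features_csv = out_dir / "features.csv"
        features.to_csv(features_csv, index=False)
        _write_meta(out_dir, "features", config)
        log.info("features: %d rows -> %s", len(features), features_csv)

        report = stats_report(features, config)
        (out_dir / "stats_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_meta(out_dir, "stats_report", config)
        pd.DataFrame(report["roc_table"]).to_csv(out_dir / "roc_report.csv", index=False)
        _write_meta(out_dir, "roc_report", config)
        log.info("stats + roc reports written")
        return out_dir
    finally:
        log.removeHandler(handler)
        handler.close()
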