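"""Quantitative habitat features: volumes (mL), volume percentages, and changes.

Per patient and time point: whole-muscle volume, the volume of each habitat
subregion (LL, HL, LH, HH), and each subregion's volume percentage
VP = subregion volume / whole volume x 100. Longitudinal change of a
feature x is reported both absolutely, delta = post - pre, and relatively,
delta% = (post - pre) / pre x 100; delta% is missing (NaN) when pre = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .habitat import HABITATS, LABELS, HabitatLabelMap, compute_cohort_thresholds, segment_patient
from .io import CohortManifest, read_mask, read_volume

__all__ = [
    "FEATURE_KEYS",
    "HabitatFeatureSet",
    "LongitudinalFeatureSet",
    "extract_features",
    "longitudinal_changes",
    "load_patient_images",
    "cohort_feature_table",
    "FEATURE_COLUMNS",
]

MM3_PER_ML = 1000.0

#: Scalar features carried through the longitudinal stage, in column order.
FEATURE_KEYS = (
    "volume_whole",
    *(f"volume_{h}" for h in HABITATS),
    *(f"vp_{h}" for h in HABITATS),
)


@dataclass(frozen=True)
class HabitatFeatureSet:
    """Volumes (mL) and volume percentages (%) for one orbit at one time point."""

    whole_volume: float
    volume: Mapping[str, float]  # mL per habitat
    vp: Mapping[str, float]  # percent per habitat

    def as_dict(self) -> dict[str, float]:
        d = {"volume_whole": self.whole_volume}
        d.update({f"volume_{h}": self.volume[h] for h in HABITATS})
        d.update({f"vp_{h}": self.vp[h] for h in HABITATS})
        return d


@dataclass(frozen=True)
class LongitudinalFeatureSet:
    """Pre/post feature sets with per-feature delta and delta%."""

    pre: HabitatFeatureSet
    post: HabitatFeatureSet
    delta: Mapping[str, float] = field(default_factory=dict)
    delta_pct: Mapping[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        row.update({f"pre_{k}": v for k, v in self.pre.as_dict().items()})
        row.update({f"post_{k}": v for k, v in self.post.as_dict().items()})
        for k in FEATURE_KEYS:
            row[f"dvol_{k[len('volume_'):]}" if k.startswith("volume_") else f"dvp_{k[len('vp_'):]}"] = self.delta[k]
            row[
                f"dpct_volume_{k[len('volume_'):]}" if k.startswith("volume_") else f"dpct_vp_{k[len('vp_'):]}"
            ] = self.delta_pct[k]
        return row


def extract_features(labels: HabitatLabelMap) -> HabitatFeatureSet:
    """Volumes and VPs from a habitat label map.

    volume(label) = voxel count x voxel volume / 1000 (mm^3 -> mL);
    the whole-muscle volume is the sum over the four habitats, which
    partition the mask exhaustively.
    """
    n_in_mask = labels.n_in_mask
    if n_in_mask == 0:
        raise ValueError("empty mask: whole-muscle volume is zero")
    vox_ml = labels.geometry.voxel_volume_mm3 / MM3_PER_ML
    counts = labels.counts()
    volume = {h: counts[h] * vox_ml for h in HABITATS}
    whole = n_in_mask * vox_ml
    vp = {h: 100.0 * counts[h] / n_in_mask for h in HABITATS}
    return HabitatFeatureSet(whole, volume, vp)


def longitudinal_changes(pre: HabitatFeatureSet, post: HabitatFeatureSet) -> LongitudinalFeatureSet:
    """Delta and delta% for every feature; delta% is NaN where pre = 0.

    Delta% of a VP is computed on the VP values themselves, matching how
    relative VP changes are reported, not re-derived from volumes.
    """
    pre_d, post_d = pre.as_dict(), post.as_dict()
    delta = {k: post_d[k] - pre_d[k] for k in FEATURE_KEYS}
    delta_pct = {
        k: (100.0 * (post_d[k] - pre_d[k]) / pre_d[k]) if pre_d[k] != 0 else float("nan")
        for k in FEATURE_KEYS
    }
    return LongitudinalFeatureSet(pre, post, delta, delta_pct)


def load_patient_images(paths: Mapping[str, "str"]) -> dict:
    """Load one patient's four channels and two masks from resolved paths."""
    return {
        "pre_water": read_volume(paths["pre_water"]),
        "pre_fat": read_volume(paths["pre_fat"]),
        "post_water": read_volume(paths["post_water"]),
        "post_fat": read_volume(paths["post_fat"]),
        "mask_pre": read_mask(paths["mask_pre"]).require_nonempty(),
        "mask_post": read_mask(paths["mask_post"]).require_nonempty(),
    }


#: Columns of the cohort feature table, after patient_id and response.
FEATURE_COLUMNS = tuple(
    [f"pre_{k}" for k in FEATURE_KEYS]
    + [f"post_{k}" for k in FEATURE_KEYS]
    + [x for k in FEATURE_KEYS for x in (
        (f"dvol_{k[7:]}", f"dpct_volume_{k[7:]}") if k.startswith("volume_") else (f"dvp_{k[3:]}", f"dpct_vp_{k[3:]}")
    )]
)


def patient_features(images: dict, thresholds) -> LongitudinalFeatureSet:
    """Segment both time points of one patient and derive longitudinal features.

    ``thresholds`` is either one cohort-level ThresholdPair or a
    {'pre': ..., 'post': ...} mapping from per-timepoint pooling.
    """
    t_pre = thresholds["pre"] if isinstance(thresholds, dict) else thresholds
    t_post = thresholds["post"] if isinstance(thresholds, dict) else thresholds
    pre_labels = segment_patient(images["pre_water"], images["pre_fat"], images["mask_pre"], t_pre)
    post_labels = segment_patient(images["post_water"], images["post_fat"], images["mask_post"], t_post)
    return longitudinal_changes(extract_features(pre_labels), extract_features(post_labels))


def cohort_feature_table(
    manifest: CohortManifest,
    thresholds=None,
    bins: int = 256,
    pooling: str = "cohort_all_timepoints",
) -> pd.DataFrame:
    """One row per patient: response label plus the flattened feature set.

    If ``thresholds`` is None, cohort thresholds are first derived from the
    pooled in-mask voxels of the whole manifest. Per-patient failures are
    collected and reported together; any failure aborts the run.
    """
    cohort_images, errors = [], []
    ids, responses = [], []
    for pid, response, paths in manifest.patients():
        try:
            cohort_images.append(load_patient_images(paths))
            ids.append(pid)
            responses.append(response)
        except Exception as exc:  # noqa: BLE001 - collected and re-raised with context
            errors.append(f"{pid}: {exc}")
    if errors:
        raise RuntimeError("failed to load patient image(s):\n" + "\n".join(errors))

    if thresholds is None:
        thresholds = compute_cohort_thresholds(cohort_images, bins=bins, pooling=pooling)

    rows = []
    for pid, response, images in zip(ids, responses, cohort_images):
        try:
            feats = patient_features(images, thresholds)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{pid}: {exc}")
            continue
        row = {"patient_id": pid, "response": response}
        row.update(feats.as_row())
        rows.append(row)
    if errors:
        raise RuntimeError("feature extraction failed for patient(s):\n" + "\n".join(errors))
    table = pd.DataFrame(rows, columns=["patient_id", "response", *FEATURE_COLUMNS])
    return table
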