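"""Habitat partition of extraocular muscles from water/fat signal intensity.

The muscle voxels of every subject (and, by default, both time points) are
pooled into one intensity histogram per channel. A single Otsu threshold is
derived per channel — the gray value maximizing the between-class variance
of the histogram split — and each channel is binarized at its threshold.
Combining the two binary maps yields four habitat subregions:

====== ============== ============= ==========================
label  water signal   fat signal    reading
====== ============== ============= ==========================
LL     low            low           inactive / fibrosis-like
HL     high           low           edema
LH     low            high          myosteatosis
HH     high           high          water-fat interface
====== ============== ============= ==========================

Conventions (fixed): a voxel is "high" iff intensity is strictly greater
than the threshold; the threshold is a histogram bin edge; Otsu ties are
broken toward the smallest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .io import Geometry, ScalarVolume, SegmentationMask, validate_aligned

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "HABITATS",
    "IntensityHistogram",
    "ThresholdPair",
    "HabitatLabelMap",
    "resample_to_reference",
    "pooled_histogram",
    "otsu_threshold",
    "cohort_thresholds",
    "compute_cohort_thresholds",
    "binarize",
    "combine_habitats",
    "segment_patient",
    "write_labelmap",
    "read_labelmap",
]

#: Habitat label encoding inside a HabitatLabelMap.
LABELS = {"background": 0, "LL": 1, "HL": 2, "LH": 3, "HH": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
HABITATS = ("LL", "HL", "LH", "HH")

DEFAULT_BINS = 256


class HistogramError(ValueError):
    """Raised for histograms on which no threshold can be derived."""


@dataclass(frozen=True)
class IntensityHistogram:
    """Equal-width intensity histogram of pooled in-mask voxels."""

    bin_edges: np.ndarray  # length B+1, strictly increasing
    counts: np.ndarray  # length B, non-negative

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise HistogramError("bin_edges must have length len(counts)+1")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise HistogramError("bin edges must be strictly increasing")
        if np.any(np.abs(widths - widths[0]) > 1e-9 * max(1.0, abs(widths[0]))):
            raise HistogramError("bins must have equal width")
        if np.any(counts < 0):
            raise HistogramError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ThresholdPair:
    """Cohort-level Otsu thresholds, one per channel."""

    t_water: float
    t_fat: float
    provenance: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {"t_water": self.t_water, "t_fat": self.t_fat, "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdPair":
        d = json.loads(Path(path).read_text())
        return cls(float(d["t_water"]), float(d["t_fat"]), d.get("provenance"))


@dataclass
class HabitatLabelMap:
    """Per-voxel habitat labels over the muscle mask (0 outside)."""

    data: np.ndarray
    geometry: Geometry
    threshold_pair: ThresholdPair | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.all(np.isin(np.unique(arr), list(LABELS.values()))):
            raise ValueError("label values must be in {0,1,2,3,4}")
        self.data = arr.astype(np.uint8, copy=False)

    def counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.data == lab)) for name, lab in LABELS.items() if lab != 0}

    @property
    def n_in_mask(self) -> int:
        return int(np.count_nonzero(self.data))


def _to_sitk(data: np.ndarray, geom: Geometry) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in geom.spacing))
    img.SetOrigin(tuple(float(o) for o in geom.origin))
    img.SetDirection(tuple(float(d) for d in geom.direction))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, Geometry]:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    geom = Geometry(tuple(img.GetSpacing()), tuple(img.GetOrigin()), tuple(img.GetDirection()))
    return data, geom


def resample_to_reference(
    moving: ScalarVolume | SegmentationMask,
    reference: ScalarVolume | SegmentationMask,
    mode: Literal["linear", "nearest"] = "linear",
) -> ScalarVolume | SegmentationMask:
    """Resample ``moving`` onto the grid of ``reference``.

    Masks must use ``mode='nearest'`` to stay binary. Voxels that fall
    outside the moving image's support are set to 0.
    """
    if isinstance(moving, SegmentationMask) and mode != "nearest":
        raise ValueError("masks must be resampled with mode='nearest'")
    if min(reference.data.shape) < 1:
        raise ValueError("degenerate reference grid")
    if validate_aligned(moving, reference):
        cls = type(moving)
        return cls(moving.data.copy(), reference.geometry)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        _to_sitk(np.asarray(moving.data, dtype=np.float64), moving.geometry),
        _to_sitk(np.zeros(reference.data.shape), reference.geometry),
        sitk.Transform(),
        interp,
        0.0,
        sitk.sitkFloat64,
    )
    data, geom = _from_sitk(out)
    if isinstance(moving, SegmentationMask):
        return SegmentationMask(np.rint(data).astype(np.uint8), geom)
    return ScalarVolume(np.clip(data, 0.0, None), geom)


def pooled_histogram(
    volumes: Sequence[ScalarVolume],
    masks: Sequence[SegmentationMask],
    bins: int = DEFAULT_BINS,
) -> IntensityHistogram:
    """Histogram of in-mask intensities pooled over all volume/mask pairs.

    Equal-width bins span the pooled [min, max] intensity range; the total
    count equals the total number of in-mask voxels.
    """
    if len(volumes) != len(masks) or not volumes:
        raise HistogramError("need equally many volumes and masks, at least one pair")
    if bins < 1:
        raise HistogramError("bins must be a positive integer")
    pooled: list[np.ndarray] = []
    for vol, mask in zip(volumes, masks):
        if not validate_aligned(vol, mask):
            raise HistogramError("volume and mask grids do not coincide")
        pooled.append(vol.data[mask.data > 0])
    values = np.concatenate(pooled)
    if values.size == 0:
        raise HistogramError("empty voxel pool: no in-mask voxels")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise HistogramError("zero-width intensity range: all pooled voxels identical")
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return IntensityHistogram(edges, counts)


def otsu_threshold(hist: IntensityHistogram) -> float:
    """Otsu's threshold on a histogram: the bin edge maximizing between-class variance.

    The candidate cuts are the interior bin edges; for a cut after bin i the
    low class holds bins 0..i and the high class bins i+1..B-1, with
    between-class variance sigma_B^2 = w0*w1*(mu0-mu1)^2 computed on bin
    centers. Ties are broken toward the smallest threshold. The returned
    value is the upper edge of the last "low" bin, so binarization with
    strict ">" reproduces the histogram split exactly.
    """
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise HistogramError("histogram has no counts")
    if np.count_nonzero(counts) < 2:
        raise HistogramError("all histogram mass in one bin: no valid split")
    centers = hist.centers
    w0 = np.cumsum(counts)[:-1]  # cut after bin i, i = 0..B-2
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(csum, w0, out=np.zeros_like(csum), where=w0 > 0)
    mu1 = np.divide(csum[-1] + counts[-1] * centers[-1] - csum, w1, out=np.zeros_like(csum), where=w1 > 0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    # ties go to the smallest threshold; cuts inside a run of empty bins are
    # mathematically tied but accumulate different rounding, so compare with
    # a relative tolerance rather than exact equality
    m = sigma_b.max()
    tol = max(abs(m), 1.0) * 1e-12
    best = int(np.flatnonzero(sigma_b >= m - tol)[0])
    return float(hist.bin_edges[best + 1])


def cohort_thresholds(
    waters: Sequence[ScalarVolume],
    fats: Sequence[ScalarVolume],
    masks: Sequence[SegmentationMask],
    bins: int = DEFAULT_BINS,
    provenance: dict | None = None,
) -> ThresholdPair:
    """Derive the water and fat Otsu thresholds from pooled in-mask voxels.

    The two channels are thresholded independently over the same voxel pool.
    """
    t_water = otsu_threshold(pooled_histogram(waters, masks, bins=bins))
    t_fat = otsu_threshold(pooled_histogram(fats, masks, bins=bins))
    info = {"bins": bins, "n_pairs": len(waters)}
    if provenance:
        info.update(provenance)
    return ThresholdPair(t_water, t_fat, info)


def compute_cohort_thresholds(
    cohort_images: Sequence[dict],
    bins: int = DEFAULT_BINS,
    pooling: Literal["cohort_all_timepoints", "per_timepoint"] = "cohort_all_timepoints",
) -> ThresholdPair | dict[str, ThresholdPair]:
    """Cohort-level thresholds from loaded patient images.

    ``cohort_images`` is a sequence of per-patient dicts with keys
    ``pre_water, pre_fat, post_water, post_fat, mask_pre, mask_post``
    (aligned per time point). With the default pooling both time points of
    every subject contribute to one pool per channel; ``per_timepoint``
    returns a separate ThresholdPair for 'pre' and 'post'.
    """
    def pool(timepoints: tuple[str, ...]) -> ThresholdPair:
        waters, fats, masks = [], [], []
        for p in cohort_images:
            for tp in timepoints:
                waters.append(p[f"{tp}_water"])
                fats.append(p[f"{tp}_fat"])
                masks.append(p[f"mask_{tp}"])
        return cohort_thresholds(
            waters, fats, masks, bins=bins,
            provenance={"pooling": "+".join(timepoints), "n_patients": len(cohort_images)},
        )

    if pooling == "cohort_all_timepoints":
        return pool(("pre", "post"))
    if pooling == "per_timepoint":
        return {"pre": pool(("pre",)), "post": pool(("post",))}
    raise ValueError(f"unknown pooling mode {pooling!r}")


def binarize(vol: ScalarVolume, mask: SegmentationMask, t: float) -> SegmentationMask:
    """In-mask voxels with intensity strictly above ``t`` become 1, else 0."""
    if not validate_aligned(vol, mask):
        raise ValueError("volume and mask grids do not coincide")
    out = ((vol.data > t) & (mask.data > 0)).astype(np.uint8)
    return SegmentationMask(out, vol.geometry)


def combine_habitats(
    water_bin: SegmentationMask,
    fat_bin: SegmentationMask,
    mask: SegmentationMask,
) -> HabitatLabelMap:
    """Combine per-channel binary maps into the four-habitat label map.

    (water, fat) -> label: (0,0) LL, (1,0) HL, (0,1) LH, (1,1) HH.
    Every in-mask voxel receives exactly one habitat label.
    """
    if not (validate_aligned(water_bin, mask) and validate_aligned(fat_bin, mask)):
        raise ValueError("binary maps and mask grids do not coincide")
    inside = mask.data > 0
    labels = np.zeros(mask.data.shape, dtype=np.uint8)
    labels[inside] = 1 + water_bin.data[inside] + 2 * fat_bin.data[inside]
    return HabitatLabelMap(labels, mask.geometry)


def segment_patient(
    water: ScalarVolume,
    fat: ScalarVolume,
    mask: SegmentationMask,
    thresholds: ThresholdPair,
) -> HabitatLabelMap:
    """Partition one muscle mask into habitats under cohort thresholds.

    The fat channel (and the mask, if needed) is resampled onto the water
    grid first; water is the delineation reference.
    """
    if not validate_aligned(fat, water):
        fat = resample_to_reference(fat, water, mode="linear")
    if not validate_aligned(mask, water):
        mask = resample_to_reference(mask, water, mode="nearest")
    mask.require_nonempty()
    wb = binarize(water, mask, thresholds.t_water)
    fb = binarize(fat, mask, thresholds.t_fat)
    out = combine_habitats(wb, fb, mask)
    out.threshold_pair = thresholds
    return out


def write_labelmap(labels: HabitatLabelMap, path: str | Path) -> None:
    """Write the label map as integer NIfTI with a JSON label-dictionary sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.data.astype(np.uint8), labels.geometry.affine()), str(path))
    sidecar = {
        "labels": {str(v): k for k, v in LABELS.items() if v != 0},
        "thresholds": None
        if labels.threshold_pair is None
        else {"t_water": labels.threshold_pair.t_water, "t_fat": labels.threshold_pair.t_fat},
    }
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_labelmap(path: str | Path) -> HabitatLabelMap:
    img = nib.load(str(path))
    return HabitatLabelMap(np.rint(np.asanyarray(img.dataobj)).astype(np.uint8), Geometry.from_affine(img.affine))
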