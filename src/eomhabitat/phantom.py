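"""Synthetic orbital phantoms with known habitat composition and remodeling.

No patient images accompany the habitat analysis, so every pipeline stage
is exercised against phantoms with planted ground truth: an ellipsoidal
"muscle" mask on an anisotropic grid, partitioned into the four tissue
classes (LL inactive/fibrosis-like, HL edema, LH myosteatosis, HH
water-fat interface) at prescribed volume fractions, with class-specific
water/fat mean intensities plus Gaussian noise. Longitudinal remodeling is
emulated by archetypes: responders shrink (edema fraction falls, the
myosteatosis fraction rises, whole-muscle volume contracts) while
non-responders grow (whole muscle and the low/low compartment expand).

Default archetype fractions are normalized group-median volume
percentages of the clinical cohort the defaults emulate, and the default
whole-volume change factors (0.90 responder, 1.14 non-responder) match the
reported median relative whole-volume changes (-10.3% / +13.8%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .habitat import HABITATS, LABELS, HabitatLabelMap
from .io import (
    Geometry,
    ScalarVolume,
    SegmentationMask,
    write_manifest,
    write_mask,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "RemodelingArchetype",
    "RESPONDER",
    "NON_RESPONDER",
    "PatientImages",
    "generate_phantom",
    "generate_patient",
    "sample_patient",
    "generate_cohort",
]

#: Default per-class (water_mean, fat_mean) signal intensities (a.u.).
DEFAULT_CLASS_MEANS: dict[str, tuple[float, float]] = {
    "LL": (30.0, 30.0),
    "HL": (80.0, 30.0),
    "LH": (30.0, 80.0),
    "HH": (80.0, 80.0),
}

#: Grid echoing a coronal orbital acquisition: 15 thick slices.
DEFAULT_SHAPE = (48, 48, 15)
DEFAULT_SPACING = (0.625, 0.625, 3.6)
DEFAULT_NOISE_SD = 5.0


class PhantomError(ValueError):
    """Raised when a phantom specification cannot be realized."""


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one water/fat phantom with ground truth."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    class_means: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    noise_sd: float = DEFAULT_NOISE_SD
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"LL": 0.25, "HL": 0.25, "LH": 0.25, "HH": 0.25}
    )
    seed: int = 0
    volume_scale: float = 1.0  # relative scaling of the ellipsoid volume
    layout: Literal["blocks", "mixed"] = "blocks"

    def __post_init__(self) -> None:
        fr = np.array([self.fractions[h] for h in HABITATS], dtype=float)
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise PhantomError(f"fractions must be >= 0 and sum to 1, got {dict(self.fractions)}")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.volume_scale <= 0:
            raise PhantomError("volume_scale must be > 0")
        w = {h: self.class_means[h][0] for h in HABITATS}
        f = {h: self.class_means[h][1] for h in HABITATS}
        if not (min(w["HL"], w["HH"]) > max(w["LL"], w["LH"])):
            raise PhantomError("water means must separate high (HL,HH) from low (LL,LH) classes")
        if not (min(f["LH"], f["HH"]) > max(f["LL"], f["HL"])):
            raise PhantomError("fat means must separate high (LH,HH) from low (LL,HL) classes")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing)


@dataclass(frozen=True)
class RemodelingArchetype:
    """Pre -> post change pattern of habitat fractions and whole-muscle volume."""

    name: Literal["responder", "non_responder"]
    pre_fractions: Mapping[str, float]
    post_fractions: Mapping[str, float]
    whole_volume_change: float  # post/pre volume factor

    def __post_init__(self) -> None:
        for fr in (self.pre_fractions, self.post_fractions):
            arr = np.array([fr[h] for h in HABITATS], dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise PhantomError(f"archetype fractions must sum to 1, got {dict(fr)}")
        if self.name == "responder":
            if not (
                self.post_fractions["HL"] < self.pre_fractions["HL"]
                and self.post_fractions["LH"] > self.pre_fractions["LH"]
                and self.whole_volume_change < 1.0
            ):
                raise PhantomError("responder archetype must shrink edema, grow myosteatosis, shrink whole muscle")
        elif self.name == "non_responder":
            if not (
                self.whole_volume_change > 1.0
                and self.post_fractions["LL"] * self.whole_volume_change > self.pre_fractions["LL"]
            ):
                raise PhantomError("non-responder archetype must grow whole muscle and the LL compartment")
        else:
            raise PhantomError(f"unknown archetype name {self.name!r}")


RESPONDER = RemodelingArchetype(
    "responder",
    pre_fractions={"LL": 0.50, "HL": 0.38, "LH": 0.07, "HH": 0.05},
    post_fractions={"LL": 0.68, "HL": 0.12, "LH": 0.16, "HH": 0.04},
    whole_volume_change=0.90,
)

NON_RESPONDER = RemodelingArchetype(
    "non_responder",
    pre_fractions={"LL": 0.74, "HL": 0.155, "LH": 0.09, "HH": 0.015},
    post_fractions={"LL": 0.86, "HL": 0.055, "LH": 0.08, "HH": 0.005},
    whole_volume_change=1.14,
)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` voxels to classes (largest remainder)."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _ellipsoid_mask(shape: tuple[int, int, int], volume_scale: float) -> np.ndarray:
    nx, ny, nz = shape
    scale = volume_scale ** (1.0 / 3.0)
    # radii chosen so the default grid yields ~4 mL of muscle, matching the
    # scale of bilateral EOM volumes seen clinically (~3-4.5 mL)
    radii = (0.28 * nx * scale, 0.28 * ny * scale, 0.28 * nz * scale)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d = ((x - cx) / radii[0]) ** 2 + ((y - cy) / radii[1]) ** 2 + ((z - cz) / radii[2]) ** 2
    return (d <= 1.0).astype(np.uint8)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, ScalarVolume, SegmentationMask, HabitatLabelMap]:
    """One water/fat phantom pair with its mask and planted habitat truth.

    Class compartments are contiguous slabs along the first axis (largest-
    remainder rounding of the fractions to whole voxels); with
    ``layout='mixed'`` the class assignment is instead a seeded voxelwise
    shuffle, stressing thresholding without spatial coherence. Identical
    specs (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape, spec.volume_scale)
    coords = np.argwhere(mask > 0)  # row-major: contiguous runs are slabs along axis 0
    n = len(coords)
    if n == 0:
        raise PhantomError("mask is empty; grid too small")
    fr = np.array([spec.fractions[h] for h in HABITATS], dtype=float)
    if np.count_nonzero(fr > 0) > n:
        raise PhantomError("mask too small to represent every nonzero class fraction")
    counts = _largest_remainder(fr, n)
    # sub-voxel fractions (f*n < 1) may round to zero voxels: the phantom
    # simply lacks that habitat, as a real muscle can
    order = np.arange(n)
    if spec.layout == "mixed":
        order = rng.permutation(n)
    truth = np.zeros(spec.shape, dtype=np.uint8)
    start = 0
    for h, c in zip(HABITATS, counts):
        sel = coords[order[start : start + c]]
        truth[sel[:, 0], sel[:, 1], sel[:, 2]] = LABELS[h]
        start += c
    water = np.zeros(spec.shape, dtype=np.float64)
    fat = np.zeros(spec.shape, dtype=np.float64)
    for h in HABITATS:
        inside = truth == LABELS[h]
        water[inside] = spec.class_means[h][0]
        fat[inside] = spec.class_means[h][1]
    if spec.noise_sd > 0:
        in_mask = mask > 0
        water[in_mask] += rng.normal(0.0, spec.noise_sd, n)
        fat[in_mask] += rng.normal(0.0, spec.noise_sd, n)
        np.clip(water, 0.0, None, out=water)
        np.clip(fat, 0.0, None, out=fat)
    geom = spec.geometry
    return (
        ScalarVolume(water, geom),
        ScalarVolume(fat, geom),
        SegmentationMask(mask, geom),
        HabitatLabelMap(truth, geom),
    )


@dataclass
class PatientImages:
    """Pre/post water-fat image quadruples for one synthetic patient."""

    pre_water: ScalarVolume
    pre_fat: ScalarVolume
    mask_pre: SegmentationMask
    truth_pre: HabitatLabelMap
    post_water: ScalarVolume
    post_fat: ScalarVolume
    mask_post: SegmentationMask
    truth_post: HabitatLabelMap
    archetype: RemodelingArchetype | None = None

    def as_dict(self) -> dict:
        return {
            "pre_water": self.pre_water,
            "pre_fat": self.pre_fat,
            "mask_pre": self.mask_pre,
            "post_water": self.post_water,
            "post_fat": self.post_fat,
            "mask_post": self.mask_post,
        }


def generate_patient(archetype: RemodelingArchetype, spec: PhantomSpec) -> PatientImages:
    """Pre phantom from the archetype's pre fractions; post phantom with the
    post fractions and the mask volume scaled by the whole-volume factor."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    pre_spec = replace(spec, fractions=dict(archetype.pre_fractions), seed=int(seeds[0]))
    post_spec = replace(
        spec,
        fractions=dict(archetype.post_fractions),
        seed=int(seeds[1]),
        volume_scale=spec.volume_scale * archetype.whole_volume_change,
    )
    pw, pf, pm, pt = generate_phantom(pre_spec)
    qw, qf, qm, qt = generate_phantom(post_spec)
    return PatientImages(pw, pf, pm, pt, qw, qf, qm, qt, archetype)


def _jitter_fractions(fractions: Mapping[str, float], jitter: float, rng: np.random.Generator) -> dict[str, float]:
    """Dirichlet perturbation centered on the archetype fractions.

    The concentration is ~2/jitter^2, so a component with fraction f has
    standard deviation about jitter * sqrt(f(1-f)/2); jitter=0 returns the
    archetype fractions unchanged.
    """
    base = np.array([fractions[h] for h in HABITATS], dtype=float)
    if jitter <= 0:
        return dict(zip(HABITATS, base))
    kappa = 2.0 / jitter**2
    alpha = np.maximum(base, 1e-6) * kappa
    sample = rng.dirichlet(alpha)
    return dict(zip(HABITATS, sample))


def sample_patient(
    archetype: RemodelingArchetype,
    base_spec: PhantomSpec,
    jitter: float,
    rng: np.random.Generator,
) -> PatientImages:
    """One cohort patient: archetype with jittered fractions, volume factor
    and baseline size, realized as a pre/post phantom pair.

    The volume-change factor gets a lognormal perturbation (sigma =
    jitter/3) and the baseline muscle size a lognormal factor (sigma =
    2*jitter), emulating between-patient anatomical variation. Jittered
    fractions may individually cross the archetype's direction invariants;
    the planted signs hold for the vast majority of patients, as in a real
    cohort.
    """
    pre_fr = _jitter_fractions(archetype.pre_fractions, jitter, rng)
    post_fr = _jitter_fractions(archetype.post_fractions, jitter, rng)
    wvc = archetype.whole_volume_change * (float(np.exp(rng.normal(0.0, jitter / 3.0))) if jitter > 0 else 1.0)
    size = float(np.exp(rng.normal(0.0, 2.0 * jitter))) if jitter > 0 else 1.0
    seed = int(rng.integers(0, 2**31 - 1))
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    spec_pre = replace(base_spec, fractions=pre_fr, seed=int(seeds[0]), volume_scale=base_spec.volume_scale * size)
    spec_post = replace(
        base_spec,
        fractions=post_fr,
        seed=int(seeds[1]),
        volume_scale=base_spec.volume_scale * size * wvc,
    )
    pw, pf, pm, pt = generate_phantom(spec_pre)
    qw, qf, qm, qt = generate_phantom(spec_post)
    return PatientImages(pw, pf, pm, pt, qw, qf, qm, qt, archetype)


def generate_cohort(
    n_responsive: int,
    n_unresponsive: int,
    out_dir: str | Path,
    base_spec: PhantomSpec | None = None,
    jitter: float = 0.15,
    seed: int = 0,
) -> Path:
    """Write a full synthetic cohort (NIfTI volumes, masks, truth maps,
    manifest.csv) under ``out_dir``; returns the manifest path.

    The manifest is consumable by :func:`eomhabitat.io.read_manifest`; per
    patient eight files are written (four channels, two masks, two truth
    label maps). Identical seeds reproduce identical cohorts.
    """
    if n_responsive < 1 or n_unresponsive < 1:
        raise PhantomError("need at least one patient per group")
    base_spec = base_spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("responsive", RESPONDER)] * n_responsive + [("unresponsive", NON_RESPONDER)] * n_unresponsive
    for i, (label, archetype) in enumerate(groups):
        pid = f"P{i + 1:03d}"
        patient = sample_patient(archetype, base_spec, jitter, rng)
        files = {}
        for key, obj, writer in (
            ("pre_water", patient.pre_water, write_volume),
            ("pre_fat", patient.pre_fat, write_volume),
            ("post_water", patient.post_water, write_volume),
            ("post_fat", patient.post_fat, write_volume),
            ("mask_pre", patient.mask_pre, write_mask),
            ("mask_post", patient.mask_post, write_mask),
        ):
            fname = f"{pid}_{key}.nii.gz"
            writer(obj, out_dir / fname)
            files[key] = fname
        for tp, truth in (("pre", patient.truth_pre), ("post", patient.truth_post)):
            nib.save(
                nib.Nifti1Image(truth.data.astype(np.uint8), truth.geometry.affine()),
                str(out_dir / f"{pid}_truth_{tp}.nii.gz"),
            )
        rows.append({"patient_id": pid, "response": label, **files})
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
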