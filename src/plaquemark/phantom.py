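"""Synthetic MR-like phantoms with planted hypointense plaque clusters.

The study data this package targets — T2-weighted 2-D mouse brain slices,
two classes (AD model vs. wild-type control), with histology as plaque
ground truth — were never deposited.  This module generates labelled
stand-ins with the statistical structure the selection method relies on:

* every slice is a filled-ellipse "brain" mask on a dark background, with
  per-slice mask size varying slightly so in-mask pixel vectors have
  different lengths (the property the elastic mapping exists to absorb);
* AD slices carry small hypointense disks ("plaques") at canonical sites
  shared by the whole AD class, perturbed per subject, so a pixel-level
  selector can generalize across subjects;
* control slices carry none; both classes share additive Gaussian noise.

Plaques darken the signal (negative contrast) because amyloid aggregates
bind iron and shorten T2 — on T2-weighted images the affected region loses
brightness.  Intensities are floating point on a 0–255 scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "LABEL_AD",
    "LABEL_CTL",
    "PhantomConfig",
    "BrainImage",
    "PlaqueRecord",
    "PlaqueMap",
    "PhantomGeometryError",
    "generate_dataset",
    "split_dataset",
    "write_dataset",
    "load_dataset",
    "read_dicom_slice",
]

LABEL_AD = "AD"
LABEL_CTL = "CTL"


class PhantomGeometryError(ValueError):
    """Plaque geometry cannot be placed inside the brain mask."""


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults are the package's study conditions.

    ``brain_shape`` gives (row, col) semi-axes in pixels of the brain
    ellipse at scale 1; each slice draws a scale factor from
    ``slice_scale_range`` so in-mask vector lengths differ across slices.
    ``plaque_contrast`` is the fractional intensity change inside a plaque
    and must be negative (hypointensity).  ``plaque_position_jitter`` is the
    standard deviation, in pixels, of the per-subject displacement of the
    class-shared canonical plaque sites.
    """

    n_ad_subjects: int = 10
    n_ctl_subjects: int = 12
    slices_per_subject: int = 6
    image_size: int = 64
    brain_shape: tuple[float, float] = (12.0, 15.0)
    base_intensity: float = 150.0
    plaque_count_per_slice: int = 5
    plaque_radius: float = 2.5
    plaque_contrast: float = -0.30
    plaque_position_jitter: float = 1.0
    noise_sigma: float = 7.5
    slice_scale_range: tuple[float, float] = (0.93, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ad_subjects, self.n_ctl_subjects, self.slices_per_subject) < 1:
            raise ValueError("subject and slice counts must be >= 1")
        if self.plaque_contrast >= 0:
            raise ValueError("plaque_contrast must be negative (hypointense)")
        if self.plaque_count_per_slice < 1:
            raise ValueError("plaque_count_per_slice must be >= 1")
        lo, hi = self.slice_scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("slice_scale_range must satisfy 0 < lo <= hi <= 1")
        a, b = self.brain_shape
        if hi * max(a, b) >= self.image_size / 2:
            raise PhantomGeometryError("brain ellipse does not fit in the image")

    @property
    def n_subjects(self) -> int:
        return self.n_ad_subjects + self.n_ctl_subjects

    @property
    def n_images(self) -> int:
        return self.n_subjects * self.slices_per_subject


@dataclass
class BrainImage:
    """One MR slice: intensity grid, binary brain mask, label, identity."""

    intensities: np.ndarray
    mask: np.ndarray
    label: str
    subject_id: str
    slice_id: int

    def __post_init__(self) -> None:
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if self.label not in (LABEL_AD, LABEL_CTL):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.slice_id)


@dataclass(frozen=True)
class PlaqueRecord:
    row: float
    col: float
    radius: float


class PlaqueMap:
    """Ground-truth plaque centers/radii per AD slice.

    A synthetic stand-in for histology: the generator records every planted
    plaque here.  Control slices have no entries.
    """

    def __init__(self) -> None:
        self._records: dict[tuple[str, int], list[PlaqueRecord]] = {}

    def add(self, key: tuple[str, int], record: PlaqueRecord) -> None:
        self._records.setdefault(key, []).append(record)

    def for_slice(self, key: tuple[str, int]) -> list[PlaqueRecord]:
        return list(self._records.get(key, []))

    def keys(self) -> list[tuple[str, int]]:
        return list(self._records)

    def total_count(self, keys: Sequence[tuple[str, int]] | None = None) -> int:
        if keys is None:
            keys = self.keys()
        return sum(len(self._records.get(k, ())) for k in keys)

    def __iter__(self) -> Iterator[tuple[tuple[str, int], list[PlaqueRecord]]]:
        return iter(self._records.items())

    def __len__(self) -> int:
        return len(self._records)


def _ellipse_mask(size: int, semi_r: float, semi_c: float) -> np.ndarray:
    center = (size - 1) / 2.0
    rr, cc = np.ogrid[:size, :size]
    return ((rr - center) / semi_r) ** 2 + ((cc - center) / semi_c) ** 2 <= 1.0


def _draw_canonical_sites(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Canonical plaque sites, one draw per dataset, in pixel offsets from center.

    Sites are confined to an inner fraction of the ellipse so that, after
    per-subject jitter and the smallest slice scale, every plaque disk stays
    inside the brain mask.  Sites are kept at least one plaque diameter
    apart so the planted clusters are distinct.
    """
    semi_r, semi_c = config.brain_shape
    s_min = config.slice_scale_range[0]
    margin = config.plaque_radius + 2.0 * config.plaque_position_jitter + 1.0
    f_max = 1.0 - margin / (s_min * min(semi_r, semi_c))
    if f_max <= 0.05:
        raise PhantomGeometryError(
            "plaque radius + jitter leave no room inside the brain ellipse"
        )
    min_sep = 2.0 * config.plaque_radius + 1.0
    # rejection sampling with restarts: a poorly placed early site can make
    # the remaining separation constraints unsatisfiable, so retry the set
    for _ in range(500):
        sites: list[np.ndarray] = []
        for _ in range(200):
            if len(sites) == config.plaque_count_per_slice:
                break
            theta = rng.uniform(0.0, 2.0 * np.pi)
            f = f_max * np.sqrt(rng.uniform())
            cand = np.array([f * semi_r * np.sin(theta), f * semi_c * np.cos(theta)])
            if all(np.hypot(*(cand - s)) >= min_sep for s in sites):
                sites.append(cand)
        if len(sites) == config.plaque_count_per_slice:
            return np.asarray(sites)
    raise PhantomGeometryError(
        "could not place the requested plaque count inside the brain ellipse"
    )


def _clamp_into_ellipse(
    offset: np.ndarray, semi_r: float, semi_c: float, margin: float
) -> np.ndarray:
    """Radially clamp a center offset so a disk of ``margin`` stays in-mask."""
    limit = 1.0 - margin / min(semi_r, semi_c)
    norm = np.hypot(offset[0] / semi_r, offset[1] / semi_c)
    if norm > limit:
        offset = offset * (limit / norm)
    return offset


def generate_dataset(config: PhantomConfig) -> tuple[list[BrainImage], PlaqueMap]:
    """Generate the labelled phantom dataset and its plaque ground truth.

    Returns ``n_subjects * slices_per_subject`` images.  AD slices contain
    exactly ``plaque_count_per_slice`` hypointense disks at the canonical
    sites perturbed by per-subject jitter; control slices contain none.
    Identical configs (same seed) produce bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    canonical = _draw_canonical_sites(config, rng)
    semi_r, semi_c = config.brain_shape
    center = (config.image_size - 1) / 2.0
    lo, hi = config.slice_scale_range

    images: list[BrainImage] = []
    plaques = PlaqueMap()
    subjects = [(f"AD{i + 1:02d}", LABEL_AD) for i in range(config.n_ad_subjects)]
    subjects += [(f"CTL{i + 1:02d}", LABEL_CTL) for i in range(config.n_ctl_subjects)]

    for subject_id, label in subjects:
        jitter = rng.normal(0.0, config.plaque_position_jitter, size=canonical.shape)
        subject_sites = canonical + jitter
        for slice_id in range(config.slices_per_subject):
            scale = rng.uniform(lo, hi)
            sr, sc = scale * semi_r, scale * semi_c
            mask = _ellipse_mask(config.image_size, sr, sc)
            signal = np.zeros((config.image_size, config.image_size))
            signal[mask] = config.base_intensity
            if label == LABEL_AD:
                rr, cc = np.ogrid[: config.image_size, : config.image_size]
                for site in subject_sites:
                    pos = _clamp_into_ellipse(
                        scale * site, sr, sc, config.plaque_radius + 0.5
                    )
                    prow, pcol = center + pos[0], center + pos[1]
                    disk = (rr - prow) ** 2 + (cc - pcol) ** 2 <= config.plaque_radius**2
                    signal[disk & mask] *= 1.0 + config.plaque_contrast
                    plaques.add(
                        (subject_id, slice_id),
                        PlaqueRecord(float(prow), float(pcol), config.plaque_radius),
                    )
            noise = rng.normal(0.0, config.noise_sigma, size=signal.shape)
            intensities = np.clip(signal + noise, 0.0, None)
            images.append(
                BrainImage(
                    intensities=intensities,
                    mask=mask,
                    label=label,
                    subject_id=subject_id,
                    slice_id=slice_id,
                )
            )
    return images, plaques


def split_dataset(
    images: Sequence[BrainImage],
    n_repeats: int = 8,
    test_composition: tuple[int, int] = (32, 20),
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Repeated random train/validation/test partitions.

    ``test_composition`` is (number of control test slices, number of AD
    test slices), drawn at the slice level as in the original protocol.
    The non-test remainder is split evenly into train and validation.
    Returns ``n_repeats`` index triples (train, validation, test); parts
    are pairwise disjoint within a repeat.
    """
    labels = np.array([im.label for im in images])
    ctl_idx = np.flatnonzero(labels == LABEL_CTL)
    ad_idx = np.flatnonzero(labels == LABEL_AD)
    n_ctl_test, n_ad_test = test_composition
    if n_ctl_test > len(ctl_idx) or n_ad_test > len(ad_idx):
        raise ValueError(
            f"test composition {test_composition} exceeds class counts "
            f"({len(ctl_idx)} CTL, {len(ad_idx)} AD)"
        )
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_repeats):
        test = np.concatenate(
            [
                rng.choice(ctl_idx, size=n_ctl_test, replace=False),
                rng.choice(ad_idx, size=n_ad_test, replace=False),
            ]
        )
        remainder = np.setdiff1d(np.arange(len(images)), test)
        remainder = rng.permutation(remainder)
        n_train = len(remainder) - len(remainder) // 2
        train, validation = remainder[:n_train], remainder[n_train:]
        partitions.append((np.sort(train), np.sort(validation), np.sort(test)))
    return partitions


# ---------------------------------------------------------------------------
# Disk I/O: 16-bit grayscale PNGs with a tab-separated manifest.

_INTENSITY_SCALE = 256.0  # 0-255 float -> uint16


def write_dataset(
    images: Sequence[BrainImage], plaques: PlaqueMap, out_dir: str | Path
) -> Path:
    """Write images/masks as PNG plus TSV manifest and plaque table."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "slice_id", "label", "image", "mask"])
        for im in images:
            stem = f"{im.subject_id}_s{im.slice_id}"
            img_rel = f"images/{stem}.png"
            mask_rel = f"masks/{stem}.png"
            arr = np.clip(im.intensities * _INTENSITY_SCALE, 0, 65535).astype(np.uint16)
            Image.fromarray(arr).save(out / img_rel)
            Image.fromarray(np.where(im.mask, 255, 0).astype(np.uint8)).save(
                out / mask_rel
            )
            writer.writerow([im.subject_id, im.slice_id, im.label, img_rel, mask_rel])
    with (out / "plaques.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "slice_id", "row", "col", "radius"])
        for key, records in plaques:
            for rec in records:
                writer.writerow([key[0], key[1], rec.row, rec.col, rec.radius])
    return manifest


def load_dataset(manifest: str | Path) -> tuple[list[BrainImage], PlaqueMap]:
    """Read a dataset written by :func:`write_dataset`."""
    from PIL import Image

    manifest = Path(manifest)
    base = manifest.parent
    images: list[BrainImage] = []
    with manifest.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            arr = np.asarray(Image.open(base / row["image"]), dtype=np.float64)
            mask = np.asarray(Image.open(base / row["mask"])) > 0
            images.append(
                BrainImage(
                    intensities=arr / _INTENSITY_SCALE,
                    mask=mask,
                    label=row["label"],
                    subject_id=row["subject_id"],
                    slice_id=int(row["slice_id"]),
                )
            )
    plaques = PlaqueMap()
    plaque_path = base / "plaques.tsv"
    if plaque_path.exists():
        with plaque_path.open() as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                plaques.add(
                    (row["subject_id"], int(row["slice_id"])),
                    PlaqueRecord(float(row["row"]), float(row["col"]), float(row["radius"])),
                )
    return images, plaques


def read_dicom_slice(path: str | Path) -> np.ndarray:
    """Read one single-frame DICOM grid as a float array (requires pydicom)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading DICOM slices requires the 'pydicom' package") from exc
    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a single-frame 2-D DICOM image")
    return arr
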