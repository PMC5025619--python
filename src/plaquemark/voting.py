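"""Vote over repeated selections and mark selected pixels on AD images."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import PixelFeatureVector, elastic_map_inverse
from .phantom import LABEL_AD, BrainImage

__all__ = ["VotingConfig", "MarkedImage", "vote", "mark_ad_images",
           "write_marks_tsv", "render_overlay"]


@dataclass(frozen=True)
class VotingConfig:
    """k repeated selections; a feature survives with more than t_select
    votes (strict comparison, as printed; ``strict=False`` relaxes to >=).
    t_select must lie in (k/2, k)."""

    k: int = 10
    t_select: int = 8
    strict: bool = True

    def __post_init__(self) -> None:
        if not (self.k / 2 < self.t_select < self.k):
            raise ValueError("t_select must lie strictly between k/2 and k")


@dataclass
class MarkedImage:
    """Marked pixel coordinates on one source slice."""

    image: BrainImage
    coords: np.ndarray  # (n, 2) rows of (row, col)


def vote(masks: Sequence[np.ndarray], config: VotingConfig) -> np.ndarray:
    """Per-feature vote count threshold across the k repeated masks."""
    if len(masks) != config.k:
        raise ValueError(f"expected {config.k} masks, got {len(masks)}")
    stacked = np.asarray([np.asarray(m, dtype=bool) for m in masks])
    if stacked.ndim != 2:
        raise ValueError("masks differ in length")
    counts = stacked.sum(axis=0)
    if config.strict:
        return counts > config.t_select
    return counts >= config.t_select


def mark_ad_images(
    final_mask: np.ndarray,
    images: Sequence[BrainImage],
    vectors: Sequence[PixelFeatureVector],
    index_maps: Sequence[np.ndarray],
    predictions: Sequence[str],
) -> list[MarkedImage]:
    """Mark the finally selected features on every AD-predicted image.

    Applies the inverse elastic map per image; images predicted as control
    are not marked.  Inputs are parallel sequences over the test images.
    """
    if not (len(images) == len(vectors) == len(index_maps) == len(predictions)):
        raise ValueError("images, vectors, index maps, predictions must align")
    selected = np.flatnonzero(np.asarray(final_mask, dtype=bool))
    marked = []
    for image, vector, index_map, pred in zip(images, vectors, index_maps, predictions):
        if pred != LABEL_AD:
            continue
        if index_map is None:
            raise ValueError(f"missing index map for {image.key}")
        coords = elastic_map_inverse(selected, vector, index_map)
        marked.append(MarkedImage(image=image, coords=coords))
    return marked


def write_marks_tsv(marked: Sequence[MarkedImage], path: str | Path) -> None:
    """BED-like records: subject, slice, row, col."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "slice_id", "row", "col"])
        for m in marked:
            for row, col in m.coords:
                writer.writerow([m.image.subject_id, m.image.slice_id, int(row), int(col)])


def render_overlay(
    marked: MarkedImage, path: str | Path, color: tuple[int, int, int] = (255, 40, 40)
) -> None:
    """Paint the marks on a grayscale export of the slice (PNG)."""
    from PIL import Image

    gray = np.clip(marked.image.intensities, 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for row, col in marked.coords:
        rgb[int(row), int(col)] = color
    Image.fromarray(rgb, mode="RGB").save(Path(path))
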