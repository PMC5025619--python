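"""Pixel feature vectors and the elastic length alignment.

Every masked slice yields a 1-D vector of its in-mask gray values in
row-major raster order.  Because brain masks differ in size, vectors have
different lengths; they are aligned onto a common template whose length is
the shortest vector in the dataset ("elastic mapping").  The alignment is
nearest-lower-index resampling,

    m(t) = floor(t * source_length / template_length),

chosen over value interpolation because the map must be invertible back to
real image pixels: every template position must name one source pixel so
that selected features can be marked on the image.  The map is
nondecreasing, and injective whenever template_length <= source_length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import BrainImage

__all__ = [
    "PixelFeatureVector",
    "FeatureMatrix",
    "extract_pixel_vector",
    "elastic_map_forward",
    "elastic_map_inverse",
    "build_feature_matrix",
    "write_feature_matrix",
    "load_feature_matrix",
]


@dataclass
class PixelFeatureVector:
    """In-mask gray values in raster order plus per-feature provenance.

    ``coords[i]`` is the (row, col) image coordinate whose intensity is
    ``values[i]``; both have length ``source_length``.
    """

    values: np.ndarray
    coords: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if len(self.values) != self.source_length or len(self.coords) != self.source_length:
            raise ValueError("values/coords length must equal source_length")


@dataclass
class FeatureMatrix:
    """Template-aligned gray matrix, template_length x n_samples.

    ``index_maps[j]`` maps template positions to source positions of sample
    ``j``; column ``j`` equals ``vectors[j].values[index_maps[j]]``.
    """

    matrix: np.ndarray
    template_length: int
    index_maps: list[np.ndarray]
    labels: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def extract_pixel_vector(image: BrainImage) -> PixelFeatureVector:
    """Extract the in-mask intensities of one slice, in raster order."""
    if not image.mask.any():
        raise ValueError("cannot extract features from an empty mask")
    rows, cols = np.nonzero(image.mask)  # row-major order
    coords = np.column_stack([rows, cols])
    values = image.intensities[rows, cols].astype(np.float64)
    return PixelFeatureVector(values=values, coords=coords, source_length=len(values))


def elastic_map_forward(
    vector: PixelFeatureVector, template_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a pixel vector onto the template length.

    Returns ``(mapped_values, index_map)`` with
    ``index_map[t] = floor(t * source_length / template_length)``.
    Raises if the template is longer than the source vector.
    """
    n = vector.source_length
    if template_length > n:
        raise ValueError(
            f"template_length {template_length} exceeds source length {n}"
        )
    if template_length < 1:
        raise ValueError("template_length must be >= 1")
    t = np.arange(template_length)
    index_map = (t * n) // template_length
    return vector.values[index_map], index_map


def elastic_map_inverse(
    selected_template_indices: Sequence[int] | np.ndarray,
    vector: PixelFeatureVector,
    index_map: np.ndarray,
) -> np.ndarray:
    """Map selected template positions back to (row, col) image coordinates.

    The returned coordinates are the provenance of the source pixels the
    forward map sampled; they always lie inside the sample's brain mask.
    """
    sel = np.asarray(selected_template_indices, dtype=np.intp)
    if sel.size and (sel.min() < 0 or sel.max() >= len(index_map)):
        raise IndexError("selected template index outside [0, template_length)")
    return vector.coords[index_map[sel]]


def build_feature_matrix(
    vectors: Sequence[PixelFeatureVector],
    labels: Sequence[str],
    normalize: bool = False,
) -> FeatureMatrix:
    """Stack elastically mapped vectors into a template x samples matrix.

    The template length is the minimum source length over the dataset.
    ``normalize`` optionally z-scores each sample's mapped values (off by
    default; the selection criterion operates on raw gray values).
    """
    if len(vectors) < 2:
        raise ValueError("need at least two samples")
    if len(vectors) != len(labels):
        raise ValueError("labels and vectors length mismatch")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes (criterion undefined)")
    template_length = min(v.source_length for v in vectors)
    columns, index_maps = [], []
    for v in vectors:
        mapped, index_map = elastic_map_forward(v, template_length)
        if normalize:
            sd = mapped.std()
            mapped = (mapped - mapped.mean()) / (sd if sd > 0 else 1.0)
        columns.append(mapped)
        index_maps.append(index_map)
    return FeatureMatrix(
        matrix=np.column_stack(columns),
        template_length=template_length,
        index_maps=index_maps,
        labels=labels,
    )


def write_feature_matrix(fm: FeatureMatrix, tsv_path: str | Path) -> None:
    """Serialize as TSV plus a JSON sidecar (template length, labels, maps)."""
    tsv_path = Path(tsv_path)
    np.savetxt(tsv_path, fm.matrix, delimiter="\t", fmt="%.6g")
    sidecar = {
        "template_length": int(fm.template_length),
        "labels": [str(x) for x in fm.labels],
        "index_maps": [m.tolist() for m in fm.index_maps],
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_matrix(tsv_path: str | Path) -> FeatureMatrix:
    tsv_path = Path(tsv_path)
    matrix = np.loadtxt(tsv_path, delimiter="\t", ndmin=2)
    sidecar = json.loads(tsv_path.with_suffix(".json").read_text())
    return FeatureMatrix(
        matrix=matrix,
        template_length=int(sidecar["template_length"]),
        index_maps=[np.asarray(m, dtype=np.intp) for m in sidecar["index_maps"]],
        labels=np.asarray(sidecar["labels"]),
    )
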