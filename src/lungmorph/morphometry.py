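"""Per-lung chord-length morphometry on 3D binary masks.

The size of a lung along an acquisition axis is summarised by the
*median chord length*: for every grid line parallel to the axis that
intersects the lung, the chord is the number of in-mask voxels on the
line times the voxel spacing along that axis, and the per-axis length is
the median over all such chords.  Counting in-mask voxels (rather than
last-minus-first extent) is robust to concavities and boundary noise;
the per-line extent is kept as a diagnostic.  A chord through a single
voxel has length one spacing (voxel-as-cell convention), so degenerate
one-voxel objects have nonzero length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .mask import AP, AXIS_LABELS, CC, LR, MaskVolume

log = logging.getLogger(__name__)

RIGHT, LEFT = 1, 2
LUNG_NAMES = {RIGHT: "right", LEFT: "left"}


@dataclass
class LungLabelMap:
    """Voxel labels 0=background, 1=right lung, 2=left lung."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def lung_mask(self, lung: int) -> np.ndarray:
        return self.labels == lung


@dataclass
class AxisChords:
    """Chord statistics for one lung along one axis."""

    median_chord_mm: float
    max_extent_mm: float
    chord_count: int
    median_span_mm: float  # per-line last-first extent, diagnostic

    def __post_init__(self) -> None:
        if not (0 < self.median_chord_mm <= self.max_extent_mm + 1e-9):
            raise ValueError(
                f"median chord {self.median_chord_mm} outside "
                f"(0, max extent {self.max_extent_mm}]"
            )


@dataclass
class AxisMetrics:
    """Per-lung morphometry: chords per axis plus volume."""

    lung: str
    axes: dict[str, AxisChords]
    volume_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")

    def median_chord(self, axis: str) -> float:
        return self.axes[axis].median_chord_mm


def split_lungs(mask: MaskVolume, orientation: str = "RAS",
                warn_size_ratio: float = 0.1) -> LungLabelMap:
    """Split a thoracic mask into right and left lungs.

    The two largest 26-connected components are kept; in RAS storage the
    component with the larger mean LR index lies on the subject's right
    and gets label 1 (the choice flips for LPS-ordered input).  Smaller
    components (noise speckles) are discarded and counted in the
    provenance record.
    """
    if mask.is_empty():
        raise ValueError("empty mask")
    lab, n = cc_label(mask.grid, connectivity=3, return_num=True)
    if n < 2:
        raise ValueError(
            "fewer than 2 connected components; not a two-lung mask "
            "(use single-lung mode on a per-lung mask)"
        )
    sizes = np.bincount(lab.ravel())[1:]  # component ids 1..n
    order = np.argsort(sizes)[::-1] + 1
    keep = order[:2]
    discarded = int(n - 2)
    discarded_voxels = int(sizes.sum() - sizes[keep - 1].sum())
    if sizes[keep[1] - 1] < warn_size_ratio * sizes[keep[0] - 1]:
        log.warning(
            "second lung component is <%.0f%% of the largest (%d vs %d "
            "voxels); the mask may contain a single lung plus noise",
            100 * warn_size_ratio, sizes[keep[1] - 1], sizes[keep[0] - 1])
    mean_lr = [np.mean(np.nonzero(lab == c)[LR]) for c in keep]
    # RAS: larger LR index = subject's right; LPS: the reverse
    right_first = mean_lr[0] > mean_lr[1]
    if orientation.upper().startswith("L"):
        right_first = not right_first
    right_c, left_c = (keep[0], keep[1]) if right_first else (keep[1], keep[0])
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[lab == right_c] = RIGHT
    labels[lab == left_c] = LEFT
    return LungLabelMap(
        labels=labels,
        spacing=mask.spacing,
        provenance={
            "n_components": int(n),
            "discarded_components": discarded,
            "discarded_voxels": discarded_voxels,
            "component_sizes": [int(sizes[keep[0] - 1]), int(sizes[keep[1] - 1])],
        },
    )


def single_lung_labelmap(mask: MaskVolume, lung: int = RIGHT) -> LungLabelMap:
    """Treat a whole mask as one lung (single-lung mode)."""
    if mask.is_empty():
        raise ValueError("empty mask")
    labels = mask.grid.astype(np.uint8) * lung
    return LungLabelMap(labels=labels, spacing=mask.spacing,
                        provenance={"single_lung": True})


def _axis_chords(sub: np.ndarray, axis: int, spacing_k: float) -> AxisChords:
    counts = sub.sum(axis=axis)
    hit = counts > 0
    chords = counts[hit] * spacing_k
    # per-line extent (last-first+1) diagnostic
    n_k = sub.shape[axis]
    moved = np.moveaxis(sub, axis, 0)
    first = np.argmax(moved, axis=0)
    last = n_k - 1 - np.argmax(moved[::-1], axis=0)
    spans = (last - first + 1)[hit] * spacing_k
    # whole-lung bounding extent along the axis
    any_along = np.any(moved.reshape(n_k, -1), axis=1)
    idx = np.nonzero(any_along)[0]
    extent = (idx[-1] - idx[0] + 1) * spacing_k
    return AxisChords(
        median_chord_mm=float(np.median(chords)),
        max_extent_mm=float(extent),
        chord_count=int(hit.sum()),
        median_span_mm=float(np.median(spans)),
    )


def axis_metrics(labelmap: LungLabelMap) -> dict[str, AxisMetrics]:
    """Compute per-lung chord metrics and volumes.

    Returns a dict keyed by lung name ("right", "left"); lungs absent
    from the label map are skipped, an entirely empty map is an error.
    """
    out: dict[str, AxisMetrics] = {}
    voxel_vol = float(np.prod(labelmap.spacing))
    for lung_id, name in LUNG_NAMES.items():
        sub = labelmap.labels == lung_id
        if not sub.any():
            continue
        axes = {
            AXIS_LABELS[k]: _axis_chords(sub, k, labelmap.spacing[k])
            for k in (LR, AP, CC)
        }
        out[name] = AxisMetrics(
            lung=name, axes=axes,
            volume_ml=float(sub.sum()) * voxel_vol / 1000.0,
        )
    if not out:
        raise ValueError("label map contains no lung voxels")
    return out


def mask_metrics(mask: MaskVolume) -> AxisMetrics:
    """Chord metrics of a whole mask treated as a single object."""
    return axis_metrics(single_lung_labelmap(mask))["right"]


def thickness_map(labelmap: LungLabelMap, axis: int = AP) -> np.ndarray:
    """Projection of segmentation thickness along an axis (mm).

    For the default anterior-posterior axis the result is an (LR, CC)
    map whose value at each position is the summed in-mask depth; zero
    where no lung is traversed.  Summing the map over its footprint and
    multiplying by the in-plane pixel area recovers the lung volume.
    """
    present = labelmap.labels > 0
    if not present.any():
        raise ValueError("label map contains no lung voxels")
    return present.sum(axis=axis) * labelmap.spacing[axis]
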