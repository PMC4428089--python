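"""Core in-memory containers for thoracic segmentation masks.

Axis semantics are fixed throughout the package: axis 0 runs left-right
(LR, increasing toward the subject's right in RAS storage), axis 1
anterior-posterior (AP), axis 2 cranial-caudal (CC, increasing toward the
head).  All physical quantities are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_LABELS = ("LR", "AP", "CC")
LR, AP, CC = 0, 1, 2

#: map from axis name to array axis
AXIS_INDEX = {"LR": LR, "AP": AP, "CC": CC}


@dataclass
class MaskVolume:
    """A 3D boolean occupancy grid with physical voxel spacing.

    Parameters
    ----------
    grid:
        Boolean array of shape (LR, AP, CC).  Any numeric array with
        values in {0, 1} is accepted and cast.
    spacing:
        Voxel spacing in mm along (LR, AP, CC).  Must be positive.
    origin:
        Physical coordinate of the voxel (0, 0, 0) centre, mm.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got ndim={grid.ndim}")
        if grid.dtype != bool:
            values = np.unique(grid)
            if not np.all(np.isin(values, (0, 1))):
                raise ValueError(
                    f"mask grid must be binary; found values {values[:5]}"
                )
            grid = grid.astype(bool)
        self.grid = grid
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive mm values, got {spacing}")
        self.spacing = spacing
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_ml(self) -> float:
        """Total segmented volume in millilitres."""
        return float(self.grid.sum()) * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskVolume):
            return NotImplemented
        return (
            self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.grid, other.grid))
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SparseAnnotation:
    """Sparse axial annotation: 2D masks on a subset of CC slices.

    Emulates manual segmentation performed on every ``step``-th axial
    slice; the full grid geometry is retained so the dense volume can be
    reconstructed on the original grid.
    """

    slices: dict[int, np.ndarray]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    step: int = 1

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("sparse annotation needs at least one annotated slice")
        indices = sorted(self.slices)
        if indices[0] < 0 or indices[-1] >= self.shape[CC]:
            raise ValueError("annotated slice index outside grid")
        in_plane = self.shape[:2]
        fixed = {}
        for i in indices:
            sl = np.asarray(self.slices[i]).astype(bool)
            if sl.shape != in_plane:
                raise ValueError(
                    f"slice {i} shape {sl.shape} != in-plane shape {in_plane}"
                )
            fixed[i] = sl
        self.slices = fixed

    @property
    def indices(self) -> list[int]:
        return sorted(self.slices)


@dataclass
class BreathPair:
    """One subject's paired end-inspiration / end-expiration masks."""

    subject_id: str
    inspiration: MaskVolume
    expiration: MaskVolume
    metrics: dict = field(default_factory=dict)  # per-phase AxisMetrics cache

    def __post_init__(self) -> None:
        if not np.allclose(self.inspiration.spacing, self.expiration.spacing,
                           rtol=1e-3):
            raise ValueError(
                "inspiration and expiration grids have incompatible spacing: "
                f"{self.inspiration.spacing} vs {self.expiration.spacing}"
            )
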