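"""Reading, writing and densifying lung segmentation masks.

Supported on-disk formats are NIfTI-1 (``.nii``/``.nii.gz``, via nibabel)
and NRRD (``.nrrd``/``.nhdr``, via SimpleITK).  On load, volumes are
reoriented to canonical RAS order so that array axes 0/1/2 always mean
left-right / anterior-posterior / cranial-caudal regardless of the
orientation stored on disk.  Chord-length morphometry is invariant to
flips within an axis, so only the axis order matters downstream.

Dense reconstruction from sparse axial annotations uses shape-based
interpolation: each missing slice is the zero-superlevel set of the
distance-weighted linear blend of its two neighbours' signed Euclidean
distance maps (positive inside).  Slices outside the annotated range are
clamped to the nearest annotated slice.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy.ndimage import distance_transform_edt

from .mask import CC, MaskVolume, SparseAnnotation

log = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _binarize(data: np.ndarray) -> np.ndarray:
    """Cast a loaded volume to boolean, accepting {0, label} encodings."""
    values = np.unique(data)
    if len(values) > 2:
        raise ValueError(
            f"not a binary mask: {len(values)} distinct values "
            f"(first few: {values[:5]})"
        )
    if not np.all(np.isin(values, (0, 1))):
        warnings.warn(
            f"binarizing mask with values {values}: nonzero -> foreground",
            stacklevel=3,
        )
    return data != 0


def read_mask(path: str | Path, expected_spacing_tolerance: float | None = None,
              expected_spacing: tuple[float, float, float] | None = None
              ) -> MaskVolume:
    """Load a mask volume and canonicalize its axes to (LR, AP, CC).

    Parameters
    ----------
    path:
        NIfTI or NRRD file.
    expected_spacing, expected_spacing_tolerance:
        If both given, raise if any loaded spacing component deviates
        from the expectation by more than the tolerance (mm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError(
                f"{path}: missing or degenerate orientation metadata; "
                "provide an explicit axis mapping in the pipeline config"
            )
        img = nib.as_closest_canonical(img)  # RAS+: axes = LR, AP, CC
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.suffix.lower() in _NRRD_SUFFIXES:
        img = sitk.ReadImage(str(path))
        img = sitk.DICOMOrient(img, "RAS")
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = tuple(float(s) for s in img.GetSpacing())
        # ITK origins live in LPS physical space; flip to RAS
        o = img.GetOrigin()
        origin = (-float(o[0]), -float(o[1]), float(o[2]))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    grid = _binarize(np.asarray(data))
    if expected_spacing is not None and expected_spacing_tolerance is not None:
        dev = np.abs(np.asarray(spacing) - np.asarray(expected_spacing))
        if np.any(dev > expected_spacing_tolerance):
            raise ValueError(
                f"{path}: spacing {spacing} deviates from expected "
                f"{expected_spacing} by more than {expected_spacing_tolerance} mm"
            )
    return MaskVolume(grid=grid, spacing=spacing, origin=origin)


def write_mask(mask: MaskVolume, path: str | Path) -> Path:
    """Write a mask as NIfTI or NRRD; spacing and origin are preserved."""
    path = Path(path)
    if mask.is_empty():
        log.warning("writing an empty (all-zero) mask to %s", path)
    data = mask.grid.astype(np.uint8)
    if _is_nifti(path):
        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix.lower() in _NRRD_SUFFIXES:
        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
        img.SetSpacing(mask.spacing)
        # our axes are RAS; ITK stores LPS physical coordinates
        img.SetDirection((-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0))
        img.SetOrigin((-mask.origin[0], -mask.origin[1], mask.origin[2]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    return path


def write_annotation(ann: SparseAnnotation, volume_path: str | Path) -> Path:
    """Store a sparse annotation as a NIfTI volume plus a JSON sidecar.

    Unannotated slices are written as zeros; the sidecar records which
    slice indices are genuine annotations and the sampling step.
    """
    volume_path = Path(volume_path)
    grid = np.zeros(ann.shape, dtype=bool)
    for i, sl in ann.slices.items():
        grid[:, :, i] = sl
    write_mask(MaskVolume(grid, ann.spacing, ann.origin), volume_path)
    sidecar = Path(str(volume_path).split(".nii")[0] + ".annotation.json")
    sidecar.write_text(json.dumps(
        {"annotated_slices": ann.indices, "step": ann.step}, indent=2))
    return volume_path


def read_annotation(volume_path: str | Path) -> SparseAnnotation:
    volume_path = Path(volume_path)
    sidecar = Path(str(volume_path).split(".nii")[0] + ".annotation.json")
    meta = json.loads(sidecar.read_text())
    vol = read_mask(volume_path)
    slices = {int(i): vol.grid[:, :, int(i)] for i in meta["annotated_slices"]}
    return SparseAnnotation(slices=slices, shape=vol.shape, spacing=vol.spacing,
                            origin=vol.origin, step=int(meta["step"]))


def _signed_distance(slice2d: np.ndarray,
                     spacing2d: tuple[float, float]) -> np.ndarray:
    """Signed Euclidean distance map of a 2D mask, positive inside (mm).

    Degenerate all-foreground / all-background slices get a constant at
    the in-plane diagonal scale so interpolation against a neighbouring
    non-degenerate slice tapers over the gap instead of jumping.
    """
    diag = float(np.hypot(slice2d.shape[0] * spacing2d[0],
                          slice2d.shape[1] * spacing2d[1]))
    if slice2d.all():
        return np.full(slice2d.shape, diag)
    if not slice2d.any():
        return np.full(slice2d.shape, -diag)
    # voxel-center EDT puts the implied boundary midway between the last
    # inside and first outside centre; shifting both maps by half a pixel
    # places it at the voxel edge, which removes the systematic dilation
    # of interpolated slices (tie blends would otherwise always round up)
    half = 0.5 * float(np.mean(spacing2d))
    inside = distance_transform_edt(slice2d, sampling=spacing2d)
    outside = distance_transform_edt(~slice2d, sampling=spacing2d)
    return np.where(slice2d, inside - half, -(outside - half))


def reconstruct_dense(ann: SparseAnnotation) -> MaskVolume:
    """Reconstruct a dense mask from sparse axial slices.

    Annotated slices pass through unchanged; strictly interior missing
    slices are shape-interpolated between their bracketing annotations;
    slices beyond the annotated range copy the nearest annotation.
    """
    indices = ann.indices
    sdf = {i: _signed_distance(ann.slices[i], ann.spacing[:2]) for i in indices}
    grid = np.zeros(ann.shape, dtype=bool)
    lo, hi = indices[0], indices[-1]
    pos = 0
    for k in range(ann.shape[CC]):
        if k in ann.slices:
            grid[:, :, k] = ann.slices[k]
        elif k < lo:
            grid[:, :, k] = ann.slices[lo]
        elif k > hi:
            grid[:, :, k] = ann.slices[hi]
        else:
            while indices[pos + 1] < k:
                pos += 1
            j0, j1 = indices[pos], indices[pos + 1]
            w = (k - j0) / (j1 - j0)
            blend = (1.0 - w) * sdf[j0] + w * sdf[j1]
            grid[:, :, k] = blend >= 0.0
    return MaskVolume(grid=grid, spacing=ann.spacing, origin=ann.origin)
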