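"""Shared fixtures: small digital shapes with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from lungmorph import MaskVolume, PhantomSpec, make_breath_pair


def digital_ellipsoid(semi_axes, spacing=(1.0, 1.0, 1.0), margin=2):
    """Boolean ellipsoid mask: voxel centres inside the analytic surface."""
    a, b, c = semi_axes
    sx, sy, sz = spacing
    nx = int(np.ceil(a / sx)) + margin
    ny = int(np.ceil(b / sy)) + margin
    nz = int(np.ceil(c / sz)) + margin
    x = (np.arange(-nx, nx + 1) * sx)[:, None, None]
    y = (np.arange(-ny, ny + 1) * sy)[None, :, None]
    z = (np.arange(-nz, nz + 1) * sz)[None, None, :]
    grid = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    return MaskVolume(grid, spacing)


def digital_box(shape_voxels, spacing=(1.0, 1.0, 1.0), pad=2):
    """Solid box of the given voxel dimensions inside a padded grid."""
    nx, ny, nz = shape_voxels
    grid = np.zeros((nx + 2 * pad, ny + 2 * pad, nz + 2 * pad), dtype=bool)
    grid[pad:pad + nx, pad:pad + ny, pad:pad + nz] = True
    return MaskVolume(grid, spacing)


def stacked_disks(radii, size=None, spacing=(1.0, 1.0, 1.0)):
    """Axial stack of disks with per-slice radius (voxels)."""
    size = size or int(np.ceil(max(radii))) + 4
    xy = (np.arange(-size, size + 1)[:, None] ** 2
          + np.arange(-size, size + 1)[None, :] ** 2)
    grid = np.stack([xy <= r * r for r in radii], axis=2)
    return MaskVolume(grid, spacing)


@pytest.fixture
def cuboid_pair():
    """Box lungs 100x150x200 mm at 1 mm spacing, CC displaced by 50 mm."""
    spec = PhantomSpec(lung_semi_axes=(50.0, 75.0, 100.0),
                       diaphragm_displacement=50.0,
                       ap_expansion=1.0, lr_expansion=1.0,
                       spacing=(1.0, 1.0, 1.0), shape="cuboid", seed=3)
    return make_breath_pair(spec)


@pytest.fixture
def dome_pair():
    """Dome lungs with known analytic CC ratio 1 + d*sqrt(2)/c."""
    spec = PhantomSpec(lung_semi_axes=(40.0, 70.0, 100.0),
                       diaphragm_displacement=40.0,
                       ap_expansion=1.3, lr_expansion=1.2,
                       spacing=(1.4, 1.4, 1.5), shape="dome", seed=7)
    return make_breath_pair(spec)
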