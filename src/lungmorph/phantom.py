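"""Synthetic breath-hold thoracic phantoms and cohorts with known ground truth.

Each phantom is a pair of binary masks (end-expiration, end-inspiration)
containing two mirrored lungs on a voxel grid at breath-hold MRI
acquisition geometry (1.4 mm in-plane, 1.5 mm slice spacing by default).
Two lung shapes are available:

* ``cuboid`` — an axis-aligned box; every chord statistic is exact
  arithmetic, which makes it the shape of choice for unit tests.
* ``dome`` — a half-ellipsoid diaphragm dome (semi-axes a, b, c) whose
  flat base is displaced caudally by ``d`` mm at inspiration, leaving a
  full-cross-section cylindrical segment of height ``d`` under the dome.
  The cranial-caudal chord through footprint position (x, y) is then
  ``d + c*sqrt(1 - (x/a)^2 - (y/b)^2)``, so the chord-length CDF is
  closed-form — ``P(L <= t) = ((t - d)/c)^2`` over the footprint — and
  the median CC chord is ``d + c/sqrt(2)``.  Chest-wall expansion scales
  the in-plane semi-axes by the AP/LR expansion factors.

Every generated pair carries a ground-truth sidecar computed through an
independent analytic/numeric-integration path that never touches the
voxel grid, so the morphometry pipeline can be validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mask import AXIS_LABELS, BreathPair, MaskVolume, SparseAnnotation

#: paper-geometry default voxel spacing, mm (in-plane, in-plane, slice)
DEFAULT_SPACING = (1.4, 1.4, 1.5)

SHAPES = ("cuboid", "dome")


class PhantomSizingError(ValueError):
    """Requested grid cannot contain the inspiration-phase lungs."""


@dataclass
class PhantomSpec:
    """Geometry of one two-lung breath-pair phantom.

    lung_semi_axes are the expiration-phase semi-axes (a, b, c) of each
    lung in mm along (LR, AP, CC); for the cuboid shape the full box
    edge lengths are (2a, 2b, 2c).  diaphragm_displacement is the added
    cranial-caudal length d at inspiration; ap_expansion / lr_expansion
    multiply the in-plane semi-axes at inspiration (values below 1 model
    paradoxical chest-wall motion and are allowed).  noise_amplitude is
    the half-width (mm) of seeded uniform jitter applied to the implicit
    surface before voxelization.
    """

    lung_semi_axes: tuple[float, float, float] = (40.0, 70.0, 140.0)
    diaphragm_displacement: float = 60.0
    ap_expansion: float = 1.4
    lr_expansion: float = 1.3
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    shape: str = "dome"
    noise_amplitude: float = 0.0
    seed: int = 0
    lung_gap_mm: float = 16.0
    margin_mm: float = 6.0
    grid_shape: tuple[int, int, int] | None = None  # explicit grid override

    def __post_init__(self) -> None:
        a, b, c = self.lung_semi_axes
        if min(a, b, c) <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.lung_semi_axes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.ap_expansion <= 0 or self.lr_expansion <= 0:
            raise ValueError("expansion factors must be positive")
        if self.shape == "dome" and self.diaphragm_displacement < 0:
            raise ValueError("dome phantom needs diaphragm_displacement >= 0")
        if self.shape == "cuboid" and 2 * c + self.diaphragm_displacement <= 0:
            raise ValueError(
                "displacement would make the inspiration CC dimension "
                "non-positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom pair (identical per lung).

    Produced by closed-form chord statistics (CC axis, volumes, cuboid)
    and dense numeric integration of the continuous chord-length
    distribution (dome LR/AP axes); never by the voxel pipeline.
    """

    median_chords_exp: dict[str, float]
    median_chords_insp: dict[str, float]
    volume_exp_ml: float
    volume_insp_ml: float

    @property
    def ratios(self) -> dict[str, float]:
        return {a: self.median_chords_insp[a] / self.median_chords_exp[a]
                for a in AXIS_LABELS}

    @property
    def changes_mm(self) -> dict[str, float]:
        return {a: self.median_chords_insp[a] - self.median_chords_exp[a]
                for a in AXIS_LABELS}

    @property
    def volume_ratio(self) -> float:
        return self.volume_insp_ml / self.volume_exp_ml

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for ax in AXIS_LABELS:
            row[f"true_{ax.lower()}_exp_mm"] = self.median_chords_exp[ax]
            row[f"true_{ax.lower()}_insp_mm"] = self.median_chords_insp[ax]
            row[f"true_{ax.lower()}_ratio"] = self.ratios[ax]
        row["true_volume_exp_ml"] = self.volume_exp_ml
        row["true_volume_insp_ml"] = self.volume_insp_ml
        row["true_volume_ratio"] = self.volume_ratio
        return row


# ---------------------------------------------------------------------------
# analytic / numeric-integration ground truth (independent of voxelization)
# ---------------------------------------------------------------------------

def _dome_inplane_median(a: float, b: float, c: float, d: float,
                         axis: str, n_grid: int = 1200) -> float:
    """Median LR or AP chord of a dome+cylinder lung by dense sampling.

    Lines parallel to the in-plane axis are parameterized by (across, z)
    with z in [-d, c]; at height z the cross-section is the ellipse with
    semi-axes (a, b) * sqrt(1 - (max(z, 0)/c)^2).  The chord lengths on
    a fine continuous grid of line positions approximate the chord-length
    distribution; the sample median converges to the distribution median.
    """
    z = np.linspace(-d, c, n_grid, endpoint=False) + (c + d) / (2 * n_grid)
    s = np.sqrt(np.clip(1.0 - (np.maximum(z, 0.0) / c) ** 2, 0.0, None))
    if axis == "LR":
        half_len, half_across = a, b
    elif axis == "AP":
        half_len, half_across = b, a
    else:
        raise ValueError(axis)
    across = np.linspace(-half_across, half_across, n_grid, endpoint=False) \
        + half_across / n_grid
    across_scaled = across[None, :] / (half_across * s[:, None] + 1e-300)
    inside = np.abs(across_scaled) < 1.0
    chords = 2.0 * half_len * s[:, None] * np.sqrt(
        np.clip(1.0 - across_scaled ** 2, 0.0, None))
    vals = chords[inside & (chords > 0)]
    return float(np.median(vals))


def phantom_truth(spec: PhantomSpec) -> PhantomTruth:
    a, b, c = spec.lung_semi_axes
    d = spec.diaphragm_displacement
    ai, bi = a * spec.lr_expansion, b * spec.ap_expansion
    if spec.shape == "cuboid":
        exp = {"LR": 2 * a, "AP": 2 * b, "CC": 2 * c}
        insp = {"LR": 2 * ai, "AP": 2 * bi, "CC": 2 * c + d}
        v_exp = 8 * a * b * c
        v_insp = 4 * ai * bi * (2 * c + d)
    else:
        exp = {
            "LR": _dome_inplane_median(a, b, c, 0.0, "LR"),
            "AP": _dome_inplane_median(a, b, c, 0.0, "AP"),
            "CC": c / math.sqrt(2.0),
        }
        insp = {
            "LR": _dome_inplane_median(ai, bi, c, d, "LR"),
            "AP": _dome_inplane_median(ai, bi, c, d, "AP"),
            "CC": d + c / math.sqrt(2.0),
        }
        v_exp = 2.0 / 3.0 * math.pi * a * b * c
        v_insp = math.pi * ai * bi * d + 2.0 / 3.0 * math.pi * ai * bi * c
    return PhantomTruth(
        median_chords_exp=exp, median_chords_insp=insp,
        volume_exp_ml=v_exp / 1000.0, volume_insp_ml=v_insp / 1000.0,
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _implicit_lung(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                   cx: float, spec: PhantomSpec, phase: str) -> np.ndarray:
    """Inside-positive implicit function (approx. mm) for one lung."""
    a, b, c = spec.lung_semi_axes
    if phase == "inspiration":
        a, b = a * spec.lr_expansion, b * spec.ap_expansion
        d = spec.diaphragm_displacement
    else:
        d = 0.0
    if spec.shape == "cuboid":
        z_top, z_lo = 0.0, -(2 * spec.lung_semi_axes[2] + d)
        return np.minimum(
            np.minimum(a - np.abs(x - cx), b - np.abs(y)),
            np.minimum(z - z_lo, z_top - z))
    # dome: half-ellipsoid cap over [0, c], cylinder segment over [-d, 0]
    rho2 = ((x - cx) / a) ** 2 + (y / b) ** 2
    zeta = np.maximum(z, 0.0) / c
    g = 1.0 - np.sqrt(rho2 + zeta ** 2)
    scale = min(a, b, c)
    return np.minimum(g * scale, z + d)


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray, float,
                                             tuple[float, float, float]]:
    a, b, c = spec.lung_semi_axes
    d = max(spec.diaphragm_displacement, 0.0)
    a_max = a * max(spec.lr_expansion, 1.0)
    b_max = b * max(spec.ap_expansion, 1.0)
    cx = spec.lung_gap_mm / 2.0 + a_max
    m = spec.margin_mm
    x_lo, x_hi = -(cx + a_max + m), cx + a_max + m
    y_lo, y_hi = -(b_max + m), b_max + m
    if spec.shape == "cuboid":
        z_lo, z_hi = -(2 * c + d + m), m
    else:
        z_lo, z_hi = -(d + m), c + m
    need = tuple(
        int(np.ceil((hi - lo) / s))
        for (lo, hi), s in zip(((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)),
                               spec.spacing))
    shape = spec.grid_shape or need
    if any(ns < nn for ns, nn in zip(shape, need)):
        raise PhantomSizingError(
            f"grid {shape} too small for the inspiration-phase lungs "
            f"(need at least {need})")
    origin = (x_lo + spec.spacing[0] / 2, y_lo + spec.spacing[1] / 2,
              z_lo + spec.spacing[2] / 2)
    xs = origin[0] + np.arange(shape[0]) * spec.spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spec.spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spec.spacing[2]
    return (xs[:, None, None], ys[None, :, None], zs[None, None, :], cx, origin)


def _voxelize_phase(spec: PhantomSpec, phase: str,
                    rng: np.random.Generator) -> MaskVolume:
    x, y, z, cx, origin = _grid_coords(spec)
    grid = np.zeros((x.shape[0], y.shape[1], z.shape[2]), dtype=bool)
    for lung_cx in (cx, -cx):  # right lung first (RAS: +LR = right)
        f = _implicit_lung(x, y, z, lung_cx, spec, phase)
        if spec.noise_amplitude > 0:
            f = f + rng.uniform(-spec.noise_amplitude, spec.noise_amplitude,
                                size=grid.shape)
        grid |= f >= 0.0
    return MaskVolume(grid=grid, spacing=spec.spacing, origin=origin)


def make_breath_pair(spec: PhantomSpec, subject_id: str = "phantom"
                     ) -> tuple[BreathPair, PhantomTruth]:
    """Voxelize a breath pair and its analytic ground-truth sidecar.

    The same seed always yields bit-identical masks; expiration is drawn
    before inspiration so jitter fields are phase-independent but
    reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    expiration = _voxelize_phase(spec, "expiration", rng)
    inspiration = _voxelize_phase(spec, "inspiration", rng)
    pair = BreathPair(subject_id=subject_id, inspiration=inspiration,
                      expiration=expiration)
    return pair, phantom_truth(spec)


def sparsify(mask: MaskVolume, step: int) -> SparseAnnotation:
    """Keep every step-th axial (CC) slice, emulating sparse manual
    segmentation; slices are retained verbatim."""
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if mask.is_empty():
        raise ValueError("cannot sparsify an empty mask")
    slices = {i: mask.grid[:, :, i].copy()
              for i in range(0, mask.shape[2], step)}
    return SparseAnnotation(slices=slices, shape=mask.shape,
                            spacing=mask.spacing, origin=mask.origin,
                            step=step)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Generator settings for a synthetic patient/control cohort.

    The cranial-caudal ratio of each subject is drawn from a group
    normal distribution (floored at 1.0: a diaphragm cannot shorten the
    lung in this motion model) and spirometry is produced through linear
    monotone links from the true CC ratio with Gaussian noise, emulating
    the strong rank association between diaphragmatic displacement and
    supine FVC / postural drop seen in diaphragmatic weakness.  Group
    centers default to a weak-diaphragm patient group (CC ratio 1.35)
    against healthy controls (1.82).
    """

    n_patients: int = 10
    n_controls: int = 6
    cc_ratio_means: tuple[float, float] = (1.35, 1.82)  # (patients, controls)
    cc_ratio_sd: float = 0.17
    link_slope: float = 75.0       # FVC_supine %pred per unit CC ratio
    link_intercept: float = -58.25
    sitting_slope: float = 60.0    # FVC_sitting link
    sitting_intercept: float = -21.0
    noise_sd: float = 5.0          # %pred noise on the FVC links
    seed: int = 0
    ap_expansion_means: tuple[float, float] = (1.40, 1.59)
    lr_expansion_means: tuple[float, float] = (1.35, 1.41)

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.cc_ratio_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class CohortSim:
    """A simulated cohort: joined table plus optional voxel phantoms."""

    table: pd.DataFrame
    pairs: dict[str, tuple[BreathPair, PhantomTruth]] = field(
        default_factory=dict)
    spec: CohortSimSpec | None = None


def _truncate(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(v, lo, hi)


def simulate_cohort(spec: CohortSimSpec, make_phantoms: bool = True,
                    phantom_template: PhantomSpec | None = None) -> CohortSim:
    """Draw a cohort of subjects with linked MRI ratios and spirometry.

    With make_phantoms=True each subject also gets a voxelized breath
    pair whose analytic CC ratio equals the drawn true ratio (the dome
    displacement is set to d = (r - 1) * c / sqrt(2)); lung size (the
    dome CC semi-axis c) varies across subjects so that size
    normalization is actually exercised.  With make_phantoms=False only
    the table is produced, which is what Monte-Carlo calibration of the
    statistics layer uses.
    """
    rng = np.random.default_rng(spec.seed)
    template = phantom_template or PhantomSpec()
    rows = []
    pairs: dict[str, tuple[BreathPair, PhantomTruth]] = {}
    groups = (["patient"] * spec.n_patients + ["control"] * spec.n_controls)
    group_idx = {"patient": 0, "control": 1}
    for i, group in enumerate(groups):
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:02d}"
        gi = group_idx[group]
        cc_true = max(1.0, float(
            rng.normal(spec.cc_ratio_means[gi], spec.cc_ratio_sd)))
        ap_exp = max(1.0, float(
            rng.normal(spec.ap_expansion_means[gi], 0.05)))
        lr_exp = max(1.0, float(
            rng.normal(spec.lr_expansion_means[gi], 0.04)))
        c_i = float(rng.normal(template.lung_semi_axes[2], 8.0))
        fvc_supine = float(_truncate(
            spec.link_intercept + spec.link_slope * cc_true
            + rng.normal(0.0, spec.noise_sd), 0.0, 130.0))
        fvc_sitting = float(_truncate(
            spec.sitting_intercept + spec.sitting_slope * cc_true
            + rng.normal(0.0, spec.noise_sd), 5.0, 130.0))
        fev1_sitting = float(_truncate(
            0.95 * fvc_sitting + rng.normal(0.0, 3.0), 0.0, 130.0))
        fev1_supine = float(_truncate(
            0.95 * fvc_supine + rng.normal(0.0, 3.0), 0.0, 130.0))
        mip = max(0.5, float(rng.normal((6.9, 8.6)[gi], (1.4, 1.5)[gi])))
        mep = max(0.5, float(rng.normal((10.0, 12.5)[gi], (1.7, 1.3)[gi])))
        co2 = max(3.0, float(rng.normal((5.4, 5.0)[gi], (0.7, 0.4)[gi])))
        subject_seed = int(rng.integers(0, 2**31 - 1))
        row = {
            "subject_id": sid, "group": group,
            "cc_ratio_true": cc_true,
            "ap_expansion": ap_exp, "lr_expansion": lr_exp,
            "fvc_sitting_pct": fvc_sitting, "fvc_supine_pct": fvc_supine,
            "fev1_sitting_pct": fev1_sitting, "fev1_supine_pct": fev1_supine,
            "mip_kpa": mip, "mep_kpa": mep, "co2_kpa": co2,
            "phantom_seed": subject_seed,
        }
        if make_phantoms:
            if template.shape == "dome":
                d_i = (cc_true - 1.0) * c_i / math.sqrt(2.0)
            else:
                d_i = (cc_true - 1.0) * 2.0 * c_i
            sub_spec = replace(
                template,
                lung_semi_axes=(template.lung_semi_axes[0],
                                template.lung_semi_axes[1], c_i),
                diaphragm_displacement=d_i,
                ap_expansion=ap_exp, lr_expansion=lr_exp,
                seed=subject_seed,
            )
            pair, truth = make_breath_pair(sub_spec, subject_id=sid)
            pairs[sid] = (pair, truth)
            row.update(truth.to_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    return CohortSim(table=table, pairs=pairs, spec=spec)
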