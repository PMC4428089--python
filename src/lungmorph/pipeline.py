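"""End-to-end orchestration: phantoms or mask files in, tables out.

A single validated config drives the whole chain — cohort/phantom
generation (or mask loading), optional sparse-annotation emulation and
dense reconstruction, lung splitting, chord morphometry, motion ratios,
and the cohort statistics battery.  Every output CSV starts with a
provenance comment line carrying the config hash and seed, and a run
with a fixed config is byte-identical when repeated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__
from .mask import AXIS_LABELS, BreathPair
from .morphometry import axis_metrics, split_lungs, thickness_map
from .pft import load_cohort
from .phantom import (CohortSimSpec, PhantomSpec, make_breath_pair,
                      simulate_cohort, sparsify)
from .io import read_mask, reconstruct_dense, write_mask
from .ratios import decompose
from .stats import analysis_battery, report_frames

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full violation list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n  " + "\n  ".join(errors))


class PhantomSettings(BaseModel):
    lung_semi_axes: tuple[float, float, float] = (40.0, 70.0, 140.0)
    spacing: tuple[float, float, float] = (1.4, 1.4, 1.5)
    shape: Literal["cuboid", "dome"] = "dome"
    noise_amplitude: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _positive(self):
        if min(self.lung_semi_axes) <= 0:
            raise ValueError("lung_semi_axes must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        return self


class CohortSettings(BaseModel):
    n_patients: int = Field(10, ge=2)
    n_controls: int = Field(6, ge=2)
    cc_ratio_means: tuple[float, float] = (1.35, 1.82)
    cc_ratio_sd: float = Field(0.17, ge=0)
    link_slope: float = 75.0
    link_intercept: float = -58.25
    noise_sd: float = Field(5.0, ge=0)


class MorphometrySettings(BaseModel):
    orientation: Literal["RAS", "LPS"] = "RAS"
    sparsify_step: Optional[int] = Field(
        2, ge=1,
        description="emulate every-N-slice manual annotation followed by "
                    "dense reconstruction; null = use masks as-is")


class StatsSettings(BaseModel):
    mode: Literal["auto", "exact", "approximate"] = "auto"
    exact_cap: int = Field(200_000, ge=1)
    include_controls_in_correlations: bool = False
    alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    mode: Literal["synthetic", "from_masks"] = "synthetic"
    seed: int = 0
    out_dir: str = "lungmorph_out"
    phantom: PhantomSettings = PhantomSettings()
    cohort: CohortSettings = CohortSettings()
    morphometry: MorphometrySettings = MorphometrySettings()
    stats: StatsSettings = StatsSettings()
    masks_manifest: Optional[str] = None
    cohort_csv: Optional[str] = None
    write_images: bool = False
    write_masks: bool = False

    @model_validator(mode="after")
    def _one_mode(self):
        if self.mode == "from_masks" and not self.masks_manifest:
            raise ValueError("from_masks mode requires masks_manifest")
        if self.mode == "synthetic" and self.masks_manifest:
            raise ValueError(
                "both run modes configured: synthetic mode must not set "
                "masks_manifest")
        return self

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        dump = self.model_dump()
        dump.pop("out_dir", None)
        canonical = json.dumps(dump, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and fully validate a YAML/JSON config file.

    All violations are collected and reported together, not just the
    first one.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"unparseable config file: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in exc.errors()]
        raise ConfigError(msgs) from exc


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _emulate_annotation(pair: BreathPair, step: int) -> BreathPair:
    """Sparsify both phases to every step-th axial slice and reconstruct."""
    return BreathPair(
        subject_id=pair.subject_id,
        inspiration=reconstruct_dense(sparsify(pair.inspiration, step)),
        expiration=reconstruct_dense(sparsify(pair.expiration, step)),
    )


def _load_pairs_from_manifest(config: PipelineConfig
                              ) -> dict[str, BreathPair]:
    manifest = pd.read_csv(config.masks_manifest, comment="#")
    required = {"subject_id", "phase", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"masks manifest missing columns: {sorted(missing)}")
    pairs: dict[str, BreathPair] = {}
    for sid, sub in manifest.groupby("subject_id"):
        phases = dict(zip(sub["phase"], sub["path"]))
        if set(phases) != {"inspiration", "expiration"}:
            raise ValueError(
                f"subject {sid}: manifest must list exactly one inspiration "
                f"and one expiration mask, got {sorted(phases)}")
        pairs[str(sid)] = BreathPair(
            subject_id=str(sid),
            inspiration=read_mask(phases["inspiration"]),
            expiration=read_mask(phases["expiration"]),
        )
    return pairs


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def _metrics_rows(sid: str, pair: BreathPair) -> list[dict]:
    rows = []
    for phase in ("inspiration", "expiration"):
        for lung, am in pair.metrics[phase].items():
            row = {"subject_id": sid, "phase": phase, "lung": lung,
                   "volume_ml": am.volume_ml}
            for ax in AXIS_LABELS:
                ch = am.axes[ax]
                row[f"{ax.lower()}_median_chord_mm"] = ch.median_chord_mm
                row[f"{ax.lower()}_max_extent_mm"] = ch.max_extent_mm
                row[f"{ax.lower()}_chord_count"] = ch.chord_count
                row[f"{ax.lower()}_median_span_mm"] = ch.median_span_mm
            rows.append(row)
    return rows


def _ratio_rows(sid: str, results: dict) -> list[dict]:
    rows = []
    for lung, res in results.items():
        row = {"subject_id": sid, "lung": lung,
               "volume_ratio": res.volume_ratio,
               "dominance": res.dominance,
               "paradoxical_axes": ";".join(res.paradoxical_axes)}
        for ax in AXIS_LABELS:
            row[f"{ax.lower()}_ratio"] = res.ratios[ax]
            row[f"{ax.lower()}_change_mm"] = res.changes_mm[ax]
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analysis end to end; returns the output manifest.

    Any stage failure is re-raised annotated with the stage and subject;
    outputs written before the failure are retained and listed in a
    MANIFEST marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# lungmorph {__version__} config_sha256={config.config_hash()} " \
             f"seed={config.seed}\n"
    manifest: dict = {"config_sha256": config.config_hash(),
                      "seed": config.seed, "version": __version__,
                      "complete": False, "outputs": []}
    stage = "setup"
    sid = ""
    try:
        stage = "input"
        cohort_frame = None
        if config.mode == "synthetic":
            sim_spec = CohortSimSpec(
                n_patients=config.cohort.n_patients,
                n_controls=config.cohort.n_controls,
                cc_ratio_means=config.cohort.cc_ratio_means,
                cc_ratio_sd=config.cohort.cc_ratio_sd,
                link_slope=config.cohort.link_slope,
                link_intercept=config.cohort.link_intercept,
                noise_sd=config.cohort.noise_sd,
                seed=config.seed,
            )
            template = PhantomSpec(
                lung_semi_axes=config.phantom.lung_semi_axes,
                spacing=config.phantom.spacing,
                shape=config.phantom.shape,
                noise_amplitude=config.phantom.noise_amplitude,
            )
            sim = simulate_cohort(sim_spec, make_phantoms=True,
                                  phantom_template=template)
            pairs = {s: p for s, (p, _) in sim.pairs.items()}
            cohort_frame = sim.table
        else:
            pairs = _load_pairs_from_manifest(config)
            if config.cohort_csv:
                cohort_frame = load_cohort(config.cohort_csv).frame

        if config.write_masks:
            stage = "write-masks"
            mask_dir = out / "masks"
            mask_dir.mkdir(exist_ok=True)
            for sid, pair in pairs.items():
                for phase in ("inspiration", "expiration"):
                    p = mask_dir / f"{sid}_{phase}.nii.gz"
                    write_mask(getattr(pair, phase), p)
                    manifest["outputs"].append(str(p))

        metrics_rows: list[dict] = []
        ratio_rows: list[dict] = []
        thick_dir = out / "thickness_maps"
        thick_dir.mkdir(exist_ok=True)
        for sid, pair in sorted(pairs.items()):
            stage = "reconstruction"
            if config.morphometry.sparsify_step:
                pair = _emulate_annotation(pair,
                                           config.morphometry.sparsify_step)
            stage = "morphometry"
            labelmaps = {
                "inspiration": split_lungs(
                    pair.inspiration,
                    orientation=config.morphometry.orientation),
                "expiration": split_lungs(
                    pair.expiration,
                    orientation=config.morphometry.orientation),
            }
            pair.metrics = {ph: axis_metrics(lm)
                            for ph, lm in labelmaps.items()}
            metrics_rows.extend(_metrics_rows(sid, pair))
            stage = "thickness-maps"
            for phase, lm in labelmaps.items():
                tmap = thickness_map(lm)
                tpath = thick_dir / f"{sid}_{phase}_ap_thickness.csv"
                np.savetxt(tpath, tmap, fmt="%.2f", delimiter=",",
                           header=header.strip("#\n "), comments="# ")
                manifest["outputs"].append(str(tpath))
                if config.write_images:
                    _save_thickness_png(
                        tmap, thick_dir / f"{sid}_{phase}_ap_thickness.png")
            stage = "ratios"
            ratio_rows.extend(_ratio_rows(sid, decompose(pair)))
        sid = ""

        stage = "tables"
        metrics_df = pd.DataFrame(metrics_rows)
        ratios_df = pd.DataFrame(ratio_rows)
        _write_csv(metrics_df, out / "axis_metrics.csv", header)
        _write_csv(ratios_df, out / "ratios.csv", header)
        manifest["outputs"] += [str(out / "axis_metrics.csv"),
                                str(out / "ratios.csv")]

        stage = "statistics"
        if cohort_frame is not None:
            combined = ratios_df[ratios_df["lung"] == "combined"]
            keep = ["subject_id", "cc_ratio", "ap_ratio", "lr_ratio",
                    "volume_ratio", "dominance"]
            joined = cohort_frame.merge(combined[keep], on="subject_id",
                                        how="left")
            missing = joined[joined["cc_ratio"].isna()]["subject_id"].tolist()
            if missing:
                raise ValueError(
                    f"subjects in cohort table without MRI ratios: {missing}")
            joined = load_cohort(joined).frame  # validate + derive PFT columns
            _write_csv(joined, out / "cohort.csv", header)
            manifest["outputs"].append(str(out / "cohort.csv"))
            if joined["group"].nunique() == 2:
                report = analysis_battery(
                    joined, mode=config.stats.mode,
                    exact_cap=config.stats.exact_cap,
                    include_controls_in_correlations=(
                        config.stats.include_controls_in_correlations),
                    alpha=config.stats.alpha)
                comp, corr = report_frames(report)
                _write_csv(comp, out / "stats_comparisons.csv", header)
                _write_csv(corr, out / "stats_correlations.csv", header)
                (out / "stats_report.txt").write_text(
                    header + _format_report(comp, corr, report))
                (out / "stats.json").write_text(json.dumps({
                    "comparisons": comp.to_dict(orient="records"),
                    "correlations": corr.to_dict(orient="records"),
                    "significant": report.significant(),
                    "alpha": report.alpha, "n_tests": report.n_tests,
                    "notes": report.notes,
                }, indent=2))
                manifest["outputs"] += [
                    str(out / "stats_comparisons.csv"),
                    str(out / "stats_correlations.csv"),
                    str(out / "stats_report.txt"), str(out / "stats.json")]

        manifest["complete"] = True
        return manifest
    except Exception as exc:
        detail = f"stage={stage}" + (f" subject={sid}" if sid else "")
        log.error("pipeline failed at %s: %s", detail, exc)
        raise RuntimeError(f"pipeline failed at {detail}: {exc}") from exc
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        (out / "provenance.json").write_text(json.dumps({
            "config_sha256": config.config_hash(), "seed": config.seed,
            "version": __version__,
            "config": config.model_dump(),
        }, indent=2))


def _save_thickness_png(tmap: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(tmap.T, origin="lower", cmap="jet", aspect="auto")
    fig.colorbar(im, ax=ax, label="AP thickness (mm)")
    ax.set_xlabel("LR voxel")
    ax.set_ylabel("CC voxel")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _format_report(comp: pd.DataFrame, corr: pd.DataFrame, report) -> str:
    lines = ["Cohort comparison (patients vs controls), Mann-Whitney", ""]
    for _, r in comp.iterrows():
        lines.append(
            f"{r['variable']:<18} patients {r['patient_median']:7.2f} "
            f"({r['patient_min']:.2f}-{r['patient_max']:.2f})   "
            f"controls {r['control_median']:7.2f} "
            f"({r['control_min']:.2f}-{r['control_max']:.2f})   "
            f"p={r['p_value']:.4g}")
    lines += ["", "Spearman correlations (patient group)", ""]
    for _, r in corr.iterrows():
        lines.append(
            f"{r['variable_a']} ~ {r['variable_b']:<18} "
            f"r={r['spearman_r']:+.3f}  p={r['p_value']:.4g}  n={int(r['n'])}")
    lines += ["", f"significant at alpha={report.alpha}: "
              + (", ".join(report.significant()) or "none")]
    return "\n".join(lines) + "\n"
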