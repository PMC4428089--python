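"""Inspiration/expiration length ratios and the diaphragm vs chest-wall
decomposition.

Per-axis lung length at each breath-hold phase is the median chord
(:mod:`lungmorph.morphometry`); dividing the inspiration length by the
expiration length normalises for lung size, so a ratio of 1.2 means a
20% length increase on that axis.  Under the anatomical attribution that
the diaphragm lengthens the lung cranial-caudally while the chest wall
expands it anterior-posteriorly and left-right, the CC ratio is read as
the diaphragmatic contribution and the AP/LR ratios as chest-wall
contributions.  Ratios below 1 (paradoxical motion) are kept and
flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mask import AXIS_LABELS, BreathPair
from .morphometry import AxisMetrics, axis_metrics, split_lungs

DIAPHRAGM_DOMINANT = "diaphragm-dominant"
CHESTWALL_DOMINANT = "chestwall-dominant"
MIXED = "mixed"


@dataclass
class RatioResult:
    """Normalized motion of one lung (or the left/right average)."""

    subject_id: str
    lung: str  # "left", "right" or "combined"
    ratios: dict[str, float]          # per axis: insp/exp median chord
    changes_mm: dict[str, float]      # per axis: insp - exp, signed
    volume_ratio: float
    dominance: str = ""
    paradoxical_axes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError(f"non-positive length ratio: {self.ratios}")
        if not self.dominance:
            self.dominance = classify_dominance(self.ratios)
        self.paradoxical_axes = [a for a, r in self.ratios.items() if r < 1.0]

    @property
    def diaphragm_component(self) -> float:
        """Cranial-caudal ratio, attributed to diaphragmatic displacement."""
        return self.ratios["CC"]

    @property
    def chestwall_components(self) -> dict[str, float]:
        """AP and LR ratios, attributed to chest-wall (thoracic) muscles."""
        return {a: self.ratios[a] for a in ("AP", "LR")}


def percent_increase(ratio: float) -> float:
    """Length ratio expressed as percent increase over expiration.

    A ratio of 1.2 is a 20% increase; ratios below 1 give negative
    percentages (paradoxical motion).
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    # scale before subtracting so decimal ratios map to round percents
    # (1.2 -> exactly 20.0)
    return ratio * 100.0 - 100.0


def classify_dominance(ratios: dict[str, float]) -> str:
    """Diaphragm- vs chest-wall-dominant motion from per-axis ratios.

    Diaphragm-dominant when the CC increase strictly exceeds both the
    AP and LR increases; exact ties with the larger chest-wall component
    are quantization artifacts and return "mixed".
    """
    cc, chest = ratios["CC"], max(ratios["AP"], ratios["LR"])
    if cc > chest:
        return DIAPHRAGM_DOMINANT
    if cc == chest:
        return MIXED
    return CHESTWALL_DOMINANT


def pair_metrics(pair: BreathPair, single_lung: bool = False
                 ) -> tuple[dict[str, AxisMetrics], dict[str, AxisMetrics]]:
    """Per-lung AxisMetrics for both phases, cached on the pair."""
    if "inspiration" not in pair.metrics:
        if single_lung:
            from .morphometry import single_lung_labelmap
            lm_in = single_lung_labelmap(pair.inspiration)
            lm_ex = single_lung_labelmap(pair.expiration)
        else:
            lm_in = split_lungs(pair.inspiration)
            lm_ex = split_lungs(pair.expiration)
        pair.metrics["inspiration"] = axis_metrics(lm_in)
        pair.metrics["expiration"] = axis_metrics(lm_ex)
    return pair.metrics["inspiration"], pair.metrics["expiration"]


def length_ratio(pair: BreathPair, axis: str, lung: str,
                 single_lung: bool = False) -> float:
    """Median-chord inspiration/expiration ratio for one axis and lung."""
    insp, exp = pair_metrics(pair, single_lung=single_lung)
    denom = exp[lung].median_chord(axis)
    if denom <= 0:
        raise ValueError(f"degenerate expiration mask: zero {axis} length")
    return insp[lung].median_chord(axis) / denom


def raw_changes(pair: BreathPair, lung: str,
                single_lung: bool = False) -> dict[str, float]:
    """Signed per-axis median-chord change in mm (inspiration - expiration)."""
    insp, exp = pair_metrics(pair, single_lung=single_lung)
    return {
        a: insp[lung].median_chord(a) - exp[lung].median_chord(a)
        for a in AXIS_LABELS
    }


def _lung_result(pair: BreathPair, lung: str,
                 insp: dict[str, AxisMetrics],
                 exp: dict[str, AxisMetrics]) -> RatioResult:
    ratios = {
        a: insp[lung].median_chord(a) / exp[lung].median_chord(a)
        for a in AXIS_LABELS
    }
    changes = {
        a: insp[lung].median_chord(a) - exp[lung].median_chord(a)
        for a in AXIS_LABELS
    }
    return RatioResult(
        subject_id=pair.subject_id, lung=lung, ratios=ratios,
        changes_mm=changes,
        volume_ratio=insp[lung].volume_ml / exp[lung].volume_ml,
    )


def decompose(pair: BreathPair, single_lung: bool = False
              ) -> dict[str, RatioResult]:
    """Full per-lung and combined decomposition of one breath pair.

    Returns results keyed "right", "left" and "combined"; the combined
    entry averages the two per-lung ratios, changes and volume ratios
    (order-independent, transparent pooling).  In single-lung mode only
    one entry plus an identical "combined" is produced.
    """
    insp, exp = pair_metrics(pair, single_lung=single_lung)
    lungs = sorted(set(insp) & set(exp))
    out = {lung: _lung_result(pair, lung, insp, exp) for lung in lungs}
    mean = lambda vals: sum(vals) / len(vals)
    out["combined"] = RatioResult(
        subject_id=pair.subject_id, lung="combined",
        ratios={a: mean([out[l].ratios[a] for l in lungs]) for a in AXIS_LABELS},
        changes_mm={a: mean([out[l].changes_mm[a] for l in lungs])
                    for a in AXIS_LABELS},
        volume_ratio=mean([out[l].volume_ratio for l in lungs]),
    )
    return out
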