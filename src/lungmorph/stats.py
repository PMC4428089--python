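"""Small-cohort nonparametric statistics: exact Mann-Whitney comparisons,
Spearman rank correlations, and median/range descriptions.

For the cohort sizes typical of rare-disease imaging pilots (here ten
patients vs six controls) asymptotic p-values are unreliable, so the
Mann-Whitney test defaults to the exact permutation null: the U
statistic is a fixed function of the pooled rank sum, and its exact
distribution over all C(n1+n2, n1) group labelings is computed by
dynamic programming over the (possibly tied, half-integer) pooled ranks.
This handles ties exactly, which textbook exact tables and scipy's exact
mode do not.  Above a configurable labeling-count cap the test falls
back to the normal approximation with tie-corrected variance and
continuity correction; every result records which path was taken.

Spearman's r is the Pearson correlation of average-method ranks; its
p-value is an exact permutation p for n <= 9 and the usual t
approximation with n-2 degrees of freedom otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_EXACT_CAP = 200_000
ALPHA = 0.05


@dataclass
class GroupComparison:
    variable: str
    n1: int
    n2: int
    median1: float
    range1: tuple[float, float]
    median2: float
    range2: tuple[float, float]
    u_stat: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.u_stat <= self.n1 * self.n2):
            raise ValueError(f"U={self.u_stat} outside [0, n1*n2]")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p={self.p_value} outside (0, 1]")


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    r: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r|={abs(self.r)} > 1")


def describe(sample) -> tuple[float, tuple[float, float]]:
    """Median and (min, max) range; even n takes the mean of the middle two."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.median(x)), (float(x.min()), float(x.max()))


def u_statistic(x, y) -> float:
    """Mann-Whitney U for x over y: pairwise wins, ties count 0.5."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def _rank_sum_distribution(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Counts of subsets of size n1 by doubled-rank sum (exact, DP).

    ranks2 are the pooled average ranks times two (integers even with
    ties).  Entry s of the returned vector counts the labelings whose
    group-1 doubled rank sum equals s.
    """
    smax = int(ranks2.sum())
    ways = np.zeros((n1 + 1, smax + 1))
    ways[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n1, 0, -1):
            ways[k, r:] += ways[k - 1, : smax + 1 - r]
    return ways[n1]


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full-labeling enumeration.

    p = P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|) under random labeling
    of the pooled sample; the permutation distribution of U is symmetric
    about n1 n2 / 2, with or without ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * sps.rankdata(pooled)).astype(int)
    dist = _rank_sum_distribution(ranks2, n1)
    total = comb(n1 + n2, n1)
    # doubled rank sum s maps to doubled U: 2U = s - n1(n1+1)
    s_obs = int(ranks2[:n1].sum())
    mu = n1 * (n1 + n2 + 1)  # mean doubled rank sum
    dev = abs(s_obs - mu)
    s_vals = np.arange(dist.size)
    count = dist[np.abs(s_vals - mu) >= dev].sum()
    return float(count / total)


def _approx_mann_whitney_p(x, y, u: float) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney(x, y, mode: str = "auto",
                 exact_cap: int = DEFAULT_EXACT_CAP,
                 variable: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney test of two independent samples.

    mode "auto" uses the exact enumeration whenever the number of
    labelings C(n1+n2, n1) does not exceed exact_cap (the default cap
    comfortably covers a 10-vs-6 design with C(16,10)=8008), otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = u_statistic(x, y)
    n_labelings = comb(len(x) + len(y), len(x))
    if mode == "exact" or (mode == "auto" and n_labelings <= exact_cap):
        p = exact_mann_whitney_p(x, y)
        method = f"exact enumeration ({n_labelings} labelings, ties averaged)"
    elif mode in ("auto", "approximate"):
        p = _approx_mann_whitney_p(x, y, u)
        method = "normal approximation (tie-corrected, continuity-corrected)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    m1, r1 = describe(x)
    m2, r2 = describe(y)
    return GroupComparison(
        variable=variable, n1=len(x), n2=len(y),
        median1=m1, range1=r1, median2=m2, range2=r2,
        u_stat=u, p_value=p, method=method,
    )


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    if denom == 0:
        raise ValueError(
            "Spearman r undefined: a variable has zero rank variance "
            "(all values tied)")
    return float((rxc * ryc).sum() / denom)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Exact permutation p: share of orderings with |r| >= |r_obs|."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (pc[0] ** 2).sum())
    r_all = pc @ rxc / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman(x, y, exact_n_max: int = 9,
             variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with exact small-n permutation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _spearman_r(rx, ry)
    if n <= exact_n_max:
        p = _exact_spearman_p(rx, ry, r)
        method = f"exact permutation over {n}! orderings"
    else:
        if abs(r) >= 1.0 - 1e-12:
            # |r|=1: only the perfect and reversed orderings attain it,
            # so the permutation p-value is exactly 2/n!
            p = min(1.0, 2.0 / math.factorial(n))
            method = "degenerate |r|=1 (permutation bound 2/n!)"
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
            method = "t approximation (df = n - 2)"
    return CorrelationResult(variables=variables, r=r, p_value=max(p, 1e-300),
                             n=n, method=method)


# ---------------------------------------------------------------------------
# cohort-level analysis battery
# ---------------------------------------------------------------------------

COMPARISON_VARIABLES = (
    "fvc_sitting_pct", "fvc_supine_pct", "delta_fvc_pct",
    "fev1_sitting_pct", "fev1_supine_pct", "mip_kpa", "mep_kpa",
    "cc_ratio", "ap_ratio", "lr_ratio",
)

CORRELATION_PAIRS = (
    ("cc_ratio", "delta_fvc_pct"),
    ("cc_ratio", "fvc_supine_pct"),
    ("cc_ratio", "fvc_sitting_pct"),
    ("cc_ratio", "mip_kpa"),
    ("cc_ratio", "mep_kpa"),
    ("ap_ratio", "fvc_supine_pct"),
)


@dataclass
class AnalysisReport:
    comparisons: list[GroupComparison]
    correlations: list[CorrelationResult]
    alpha: float
    n_tests: int
    notes: list[str]

    def significant(self) -> list[str]:
        sig = [c.variable for c in self.comparisons if c.p_value < self.alpha]
        sig += ["~".join(c.variables) for c in self.correlations
                if c.p_value < self.alpha]
        return sig

    def comparison(self, variable: str) -> GroupComparison:
        for c in self.comparisons:
            if c.variable == variable:
                return c
        raise KeyError(variable)

    def correlation(self, var_a: str, var_b: str) -> CorrelationResult:
        for c in self.correlations:
            if set(c.variables) == {var_a, var_b}:
                return c
        raise KeyError((var_a, var_b))


def analysis_battery(joined: pd.DataFrame, mode: str = "auto",
                     exact_cap: int = DEFAULT_EXACT_CAP,
                     include_controls_in_correlations: bool = False,
                     alpha: float = ALPHA) -> AnalysisReport:
    """Run the full cohort analysis grid.

    joined must carry group labels ("patient"/"control"), the per-axis
    MRI ratios (cc_ratio, ap_ratio, lr_ratio) and the spirometry columns.
    Group comparisons are run for every available variable; rank
    correlations between MRI ratios and spirometry are computed within
    the patient group only unless include_controls_in_correlations is
    set (sensitivity analysis).
    """
    required = {"group"}
    missing = required - set(joined.columns)
    if missing:
        raise ValueError(f"joined table missing columns: {sorted(missing)}")
    patients = joined[joined["group"] == "patient"]
    controls = joined[joined["group"] == "control"]
    if len(patients) == 0 or len(controls) == 0:
        raise ValueError("need both patient and control rows")
    notes: list[str] = []
    comparisons = []
    for var in COMPARISON_VARIABLES:
        if var not in joined.columns:
            notes.append(f"variable absent, comparison skipped: {var}")
            continue
        xv = patients[var].dropna().to_numpy()
        yv = controls[var].dropna().to_numpy()
        if len(xv) == 0 or len(yv) == 0:
            notes.append(f"no data in one group, comparison skipped: {var}")
            continue
        comparisons.append(
            mann_whitney(xv, yv, mode=mode, exact_cap=exact_cap, variable=var))
    corr_frame = joined if include_controls_in_correlations else patients
    if include_controls_in_correlations:
        notes.append("correlations include controls (sensitivity analysis)")
    correlations = []
    for var_a, var_b in CORRELATION_PAIRS:
        if var_a not in corr_frame.columns or var_b not in corr_frame.columns:
            notes.append(f"correlation skipped: {var_a} ~ {var_b}")
            continue
        sub = corr_frame[[var_a, var_b]].dropna()
        if len(sub) < 3:
            notes.append(f"too few pairs, correlation skipped: {var_a} ~ {var_b}")
            continue
        correlations.append(
            spearman(sub[var_a], sub[var_b], variables=(var_a, var_b)))
    n_tests = len(comparisons) + len(correlations)
    notes.append(f"{n_tests} tests run; no multiple-testing correction applied")
    return AnalysisReport(comparisons=comparisons, correlations=correlations,
                          alpha=alpha, n_tests=n_tests, notes=notes)


def report_frames(report: AnalysisReport
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular (CSV-ready) views of an analysis report."""
    comp = pd.DataFrame([{
        "variable": c.variable,
        "patient_median": c.median1,
        "patient_min": c.range1[0], "patient_max": c.range1[1],
        "control_median": c.median2,
        "control_min": c.range2[0], "control_max": c.range2[1],
        "n_patients": c.n1, "n_controls": c.n2,
        "U": c.u_stat, "p_value": c.p_value, "method": c.method,
    } for c in report.comparisons])
    corr = pd.DataFrame([{
        "variable_a": c.variables[0], "variable_b": c.variables[1],
        "spearman_r": c.r, "p_value": c.p_value, "n": c.n, "method": c.method,
    } for c in report.correlations])
    return comp, corr
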