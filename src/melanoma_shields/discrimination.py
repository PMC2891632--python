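"""Discrimination statistics: ROC curves, Mann-Whitney AUC, Hanley
standard errors, correlated AUC comparison, cutoff selection and
binomial proportion intervals.

The AUC is computed as the Mann-Whitney probability that a randomly
chosen case scores above a randomly chosen control (ties count 1/2),
which equals the trapezoidal area under the empirical ROC curve.  Its
standard error uses the Hanley-McNeil approximation

    SE^2 = [A(1-A) + (n_case-1)(Q1-A^2) + (n_ctrl-1)(Q2-A^2)]
           / (n_case * n_ctrl),
    Q1 = A/(2-A),  Q2 = 2A^2/(1+A),

and two correlated AUCs measured on the same patients are compared with
the z statistic (A_a - A_b)/sqrt(SE_a^2 + SE_b^2 - 2 r SE_a SE_b),
where r is taken as the mean of the within-case and within-control
Pearson correlations between the two scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "AucComparison",
    "CutoffResult",
    "SensSpecResult",
    "auc_mann_whitney",
    "roc_curve",
    "hanley_se",
    "hanley_ci",
    "compare_auc_correlated",
    "sens_spec_curves",
    "confusion_at_cutoff",
    "proportion_ci",
    "plan_sensitivity_ci",
]

Z95 = 1.96


@dataclass
class RocResult:
    """Empirical ROC curve: threshold grid (with -inf/+inf sentinels),
    aligned sensitivity/specificity, trapezoidal AUC, Hanley SE and
    95% CI (clipped to [0, 1])."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se_hanley: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    r: float
    z: float
    p_two_sided: float


@dataclass
class CutoffResult:
    """Confusion counts at one cutoff (positive = score strictly above),
    with exact Clopper-Pearson 95% CIs on sensitivity and specificity."""

    cutoff: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]


@dataclass
class SensSpecResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both labels (cases and controls) must be present")
    return scores[labels == 1], scores[labels == 0]


def auc_mann_whitney(case_scores, control_scores) -> float:
    """P(case > control) + 1/2 P(case = control), via midranks."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or control_scores is None or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return float((r_cases - n1 * (n1 + 1) / 2) / (n1 * n0))


def hanley_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil SE of an AUC; Q1 pairs with (n_cases - 1)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("SE is degenerate for AUC of exactly 0 or 1")
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_cases - 1) * (q1 - auc * auc)
        + (n_controls - 1) * (q2 - auc * auc)
    ) / (n_cases * n_controls)
    return math.sqrt(var)


def hanley_ci(
    auc: float, n_cases: int, n_controls: int
) -> tuple[float, tuple[float, float]]:
    """(SE, 95% CI) for an AUC; the Wald interval is clipped to [0, 1]."""
    se = hanley_se(auc, n_cases, n_controls)
    lo = max(0.0, auc - Z95 * se)
    hi = min(1.0, auc + Z95 * se)
    return se, (lo, hi)


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all distinct score thresholds.

    A patient is called positive iff score > threshold, so sensitivity
    is non-increasing and specificity non-decreasing along the
    (ascending) threshold grid, which carries -inf/+inf sentinels.
    """
    cases, controls = _split(scores, labels)
    uniq = np.unique(np.concatenate([cases, controls]))
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    auc = auc_mann_whitney(cases, controls)
    if 0.0 < auc < 1.0 and cases.size >= 2 and controls.size >= 2:
        se, ci = hanley_ci(auc, cases.size, controls.size)
    else:
        se, ci = float("nan"), (auc, auc)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        se_hanley=se,
        ci95=ci,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def _within_group_r(a_vals: np.ndarray, b_vals: np.ndarray) -> float | None:
    # sentinel (+/-inf) scores cannot enter a Pearson correlation; drop
    # those pairs for the r estimate only
    mask = np.isfinite(a_vals) & np.isfinite(b_vals)
    a_vals, b_vals = a_vals[mask], b_vals[mask]
    if a_vals.size < 2 or np.ptp(a_vals) == 0 or np.ptp(b_vals) == 0:
        return None
    return float(stats.pearsonr(a_vals, b_vals)[0])


def compare_auc_correlated(scores_a, scores_b, labels) -> AucComparison:
    """Hanley correlated-AUC comparison of two markers measured on the
    same patients.

    r averages the within-case and within-control Pearson correlations
    of the two scores (groups with a constant score contribute
    nothing).  A zero-variance denominator (e.g. identical scores)
    returns z = 0, p = 1 by convention.
    """
    a_cases, a_controls = _split(scores_a, labels)
    b_cases, b_controls = _split(scores_b, labels)

    auc_a = auc_mann_whitney(a_cases, a_controls)
    auc_b = auc_mann_whitney(b_cases, b_controls)

    rs = [
        r
        for r in (
            _within_group_r(a_cases, b_cases),
            _within_group_r(a_controls, b_controls),
        )
        if r is not None
    ]
    if not rs:
        raise ValueError("zero score variance within both groups")
    r = float(np.mean(rs))

    n1, n0 = a_cases.size, a_controls.size
    se_a = hanley_se(min(max(auc_a, 1e-12), 1 - 1e-12), n1, n0)
    se_b = hanley_se(min(max(auc_b, 1e-12), 1 - 1e-12), n1, n0)
    var = se_a * se_a + se_b * se_b - 2.0 * r * se_a * se_b
    if var <= 0 or np.allclose(np.asarray(scores_a, float), np.asarray(scores_b, float)):
        z = 0.0
    else:
        z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, r=r, z=z, p_two_sided=min(p, 1.0))


def sens_spec_curves(scores, labels, grid=None) -> SensSpecResult:
    """Sensitivity and specificity as functions of the cutoff, with the
    intersection cutoff.

    The grid defaults to the sorted distinct scores.  Sensitivity
    (non-increasing) and specificity (non-decreasing) cross once; the
    cutoff is placed at the grid point where they are equal, or by
    linear interpolation between the adjacent grid points bracketing
    the crossing.
    """
    cases, controls = _split(scores, labels)
    if grid is None:
        grid = np.unique(np.concatenate([cases, controls]))
    else:
        grid = np.sort(np.asarray(grid, dtype=float))
    sens = np.array([(cases > t).mean() for t in grid])
    spec = np.array([(controls <= t).mean() for t in grid])
    d = sens - spec  # non-increasing in t

    idx = np.flatnonzero(d <= 0)
    if idx.size == 0:  # curves never meet on the grid: take closest end
        i = int(np.argmin(np.abs(d)))
        cutoff, s_at, p_at = float(grid[i]), float(sens[i]), float(spec[i])
    else:
        i = int(idx[0])
        if d[i] == 0 or i == 0:
            cutoff, s_at, p_at = float(grid[i]), float(sens[i]), float(spec[i])
        else:
            # crossing between grid[i-1] (d>0) and grid[i] (d<0)
            f = d[i - 1] / (d[i - 1] - d[i])
            cutoff = float(grid[i - 1] + f * (grid[i] - grid[i - 1]))
            s_at = float(sens[i - 1] + f * (sens[i] - sens[i - 1]))
            p_at = float(spec[i - 1] + f * (spec[i] - spec[i - 1]))
    return SensSpecResult(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        cutoff=cutoff,
        sens_at_cutoff=s_at,
        spec_at_cutoff=p_at,
    )


def confusion_at_cutoff(scores, labels, cutoff: float) -> CutoffResult:
    """2x2 confusion at a cutoff (positive iff score > cutoff) with
    exact 95% CIs on sensitivity and specificity."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    cases, controls = _split(scores, labels)
    tp = int((cases > cutoff).sum())
    fn = int(cases.size - tp)
    fp = int((controls > cutoff).sum())
    tn = int(controls.size - fp)
    return CutoffResult(
        cutoff=float(cutoff),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=tp / cases.size,
        specificity=tn / controls.size,
        sens_ci=proportion_ci(tp, cases.size),
        spec_ci=proportion_ci(tn, controls.size),
    )


def proportion_ci(
    successes: int,
    n: int,
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> tuple[float, float]:
    """Binomial proportion CI: exact Clopper-Pearson (default, from
    beta quantiles) or Wilson score."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if method == "clopper_pearson":
        ci = stats.binomtest(successes, n).proportion_ci(
            confidence_level=level, method="exact"
        )
    elif method == "wilson":
        ci = stats.binomtest(successes, n).proportion_ci(
            confidence_level=level, method="wilson"
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(ci.low), float(ci.high)


def plan_sensitivity_ci(
    expected_sensitivity: float, n_cases: int
) -> tuple[float, float]:
    """Design-stage CI for a sensitivity estimated from ``n_cases``
    cases: Clopper-Pearson on floor(expected * n) successes."""
    if not 0.0 < expected_sensitivity < 1.0:
        raise ValueError("expected_sensitivity must be in (0, 1)")
    k = math.floor(expected_sensitivity * n_cases)
    return proportion_ci(k, n_cases, method="clopper_pearson")
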