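"""Association statistics for case-control cohorts.

2x2 contingency machinery (Woolf odds-ratio CI, two-sided Fisher exact
test), univariable logistic regression fitted by iteratively
reweighted least squares, unpaired/paired t tests, Pearson correlation,
and the per-marker association table (group summaries, odds ratios,
CIs and p values for LVD, LVI, Breslow thickness and the log10 Shields
index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort
from .shields_index import score_cohort

__all__ = [
    "TwoByTwo",
    "OrResult",
    "LogisticFit",
    "odds_ratio_woolf",
    "fisher_exact_two_sided",
    "logistic_univariable",
    "t_test_unpaired",
    "t_test_paired",
    "pearson_correlation",
    "association_report",
]

Z95 = 1.96


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class OrResult:
    odds_ratio: float
    ci95: tuple[float, float]
    method: str = "woolf"


@dataclass
class LogisticFit:
    """Univariable logistic fit logit P(y=1) = intercept + slope * x."""

    intercept: float
    slope: float
    or_per_unit: float
    ci95: tuple[float, float]
    se_slope: float
    converged: bool
    iterations: int
    p_wald: float
    message: str = ""


def odds_ratio_woolf(table: TwoByTwo, haldane: bool = False) -> OrResult:
    """Cross-product odds ratio with the Woolf (log-scale Wald) 95% CI,
    SE = sqrt(1/a + 1/b + 1/c + 1/d).

    Zero cells raise unless ``haldane=True``, which adds 0.5 to every
    cell (Haldane-Anscombe correction).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(math.log(orr) - Z95 * se), math.exp(math.log(orr) + Z95 * se))
    method = "woolf_haldane" if (haldane and min(table.a, table.b, table.c, table.d) == 0) else "woolf"
    return OrResult(odds_ratio=orr, ci95=ci, method=method)


def fisher_exact_two_sided(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric point
    probabilities not exceeding that of the observed table (to relative
    tolerance ~1e-7), over all tables with the observed margins."""
    if table.a + table.b < 1 or table.c + table.d < 1:
        raise ValueError("each row margin must be >= 1")
    if table.a + table.c < 1 or table.b + table.d < 1:
        raise ValueError("each column margin must be >= 1")
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable sum of y*log(mu) + (1-y)*log(1-mu)
    return float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def logistic_univariable(
    x,
    y,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood univariable logistic regression by IRLS
    (Newton-Raphson).

    Convergence when the score's max absolute component falls below
    ``score_tol`` or the relative log-likelihood change below
    ``ll_tol`` (at most ``max_iter`` iterations).  Under perfect
    separation the fit is flagged non-converged with NaN estimates and
    a diagnostic message.  The CI is a Wald interval on exp(slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    converged = False
    it = 0
    message = ""
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation)"
            break
        beta = beta + step
        ll = _log_likelihood(X @ beta, y)
        if np.max(np.abs(score)) < score_tol or (
            np.isfinite(ll_old) and abs(ll - ll_old) < ll_tol * (abs(ll) + ll_tol)
        ):
            converged = True
            break
        ll_old = ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    fitted_extreme = np.all((mu > 1 - 1e-6) == (y == 1)) and np.all(
        (mu < 1e-6) == (y == 0)
    )
    if not converged or fitted_extreme or abs(beta[1]) > 1e3:
        if not message:
            message = "perfect separation suspected: estimates diverge"
        return LogisticFit(
            intercept=math.nan,
            slope=math.nan,
            or_per_unit=math.nan,
            ci95=(math.nan, math.nan),
            se_slope=math.nan,
            converged=False,
            iterations=it,
            p_wald=math.nan,
            message=message,
        )

    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se
    with np.errstate(over="ignore"):
        # a near-separated fit can have a finite slope with a huge Wald
        # SE; the CI bound saturates at inf rather than overflowing
        or_point = float(np.exp(beta[1]))
        ci = (float(np.exp(beta[1] - Z95 * se)), float(np.exp(beta[1] + Z95 * se)))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        or_per_unit=or_point,
        ci95=ci,
        se_slope=se,
        converged=True,
        iterations=it,
        p_wald=float(2 * stats.norm.sf(abs(z))),
    )


def t_test_unpaired(x1, x2, equal_variance: bool = True) -> tuple[float, float, float]:
    """Two-sample t test, Student (pooled) by default, Welch optional.
    Returns (t, df, two-sided p)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if equal_variance and np.ptp(np.concatenate([x1, x2])) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x1, x2, equal_var=equal_variance)
    if not math.isfinite(res.statistic):
        raise ValueError("degenerate variance")
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_test_paired(x, y) -> tuple[float, float, float]:
    """Paired t test (one-sample t on differences); returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    if np.all(diffs == diffs[0]) and diffs[0] != 0:
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = stats.ttest_rel(x, y)
    t = 0.0 if np.all(diffs == 0) else float(res.statistic)
    p = 1.0 if np.all(diffs == 0) else float(res.pvalue)
    return t, float(x.size - 1), p


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Sample Pearson correlation; returns (r, r^2, two-sided p) with
    the p value from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)


def lvi_two_by_two(cohort: Cohort) -> TwoByTwo:
    """Cross-tabulate lymphatic vessel invasion against outcome."""
    a = sum(1 for r in cohort if r.is_case and r.lvi)
    b = sum(1 for r in cohort if r.is_case and not r.lvi)
    c = sum(1 for r in cohort if (not r.is_case) and r.lvi)
    d = sum(1 for r in cohort if (not r.is_case) and not r.lvi)
    return TwoByTwo(a, b, c, d)


def association_report(cohort: Cohort) -> pd.DataFrame:
    """Per-marker association table for a cohort.

    One row each for LVD, LVI, Breslow thickness and the log10 Shields
    index: group summaries (mean/SD for continuous markers, count and
    percent for LVI), the odds ratio per unit (univariable logistic;
    Woolf cross-product OR for LVI, which the logistic fit on the 0/1
    covariate reproduces), its 95% CI and p value.  Zero-index records
    are excluded from the log-index row (none arise at positive LVD).
    """
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise ValueError("both outcome groups must be non-empty")
    scored = score_cohort(cohort, variant="total")
    y = scored.labels().astype(float)

    rows = []

    def continuous_row(name, values, y_values):
        keep = np.isfinite(values)
        fit = logistic_univariable(values[keep], y_values[keep])
        cases = values[keep][y_values[keep] == 1]
        controls = values[keep][y_values[keep] == 0]
        rows.append(
            {
                "marker": name,
                "case_summary": f"{cases.mean():.2f} ({cases.std(ddof=1):.2f})",
                "control_summary": f"{controls.mean():.2f} ({controls.std(ddof=1):.2f})",
                "case_mean": cases.mean(),
                "case_sd": cases.std(ddof=1),
                "control_mean": controls.mean(),
                "control_sd": controls.std(ddof=1),
                "odds_ratio": fit.or_per_unit,
                "ci_low": fit.ci95[0],
                "ci_high": fit.ci95[1],
                "p": fit.p_wald,
            }
        )

    lvd = np.array([s.lvd_used for s in scored.scores])
    continuous_row("lvd_total_mm2", lvd, y)

    tab = lvi_two_by_two(cohort)
    orr = odds_ratio_woolf(tab, haldane=min(tab.a, tab.b, tab.c, tab.d) == 0)
    fit_lvi = logistic_univariable(
        np.array([float(r.lvi) for r in scored.records]), y
    )
    rows.append(
        {
            "marker": "lvi",
            "case_summary": f"{tab.a} ({100 * tab.a / (tab.a + tab.b):.0f}%)",
            "control_summary": f"{tab.c} ({100 * tab.c / (tab.c + tab.d):.0f}%)",
            "case_mean": tab.a,
            "case_sd": np.nan,
            "control_mean": tab.c,
            "control_sd": np.nan,
            "odds_ratio": orr.odds_ratio,
            "ci_low": orr.ci95[0],
            "ci_high": orr.ci95[1],
            "p": fit_lvi.p_wald if fit_lvi.converged else fisher_exact_two_sided(tab),
        }
    )

    thick = np.array([s.thickness_mm for s in scored.scores])
    continuous_row("breslow_mm", thick, y)

    logidx = scored.log10_values(fill=np.nan)
    continuous_row("log10_shields_index", logidx, y)

    return pd.DataFrame(rows).set_index("marker")
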