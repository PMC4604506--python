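"""Outcome statistics relating volumetric measures to surgical outcome.

Engel classes are dichotomized into a satisfactory (class I) and an
unsatisfactory (classes II-IV) outcome. Three kinds of analysis are then
run on the per-subject volumetrics:

* paired t tests (pre- vs post-resection abnormality volume, or FDG vs FMZ),
  with the 95 % CI of the mean difference;
* independent-samples t tests comparing outcome subgroups, pooled-variance
  (classic Student) by default with Welch as an option;
* univariate logistic regressions of the class-I outcome on each volumetric
  predictor, reporting the odds ratio per unit, its Wald 95 % CI and p
  value, and the C-statistic (area under the ROC curve of the fitted
  probabilities).

Alpha is 0.05 two-sided throughout and no multiple-testing correction is
applied; the report records how many tests it ran so readers can judge
that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "StatResult",
    "CohortReport",
    "dichotomize",
    "paired_t",
    "independent_t",
    "logistic_single",
    "cohort_report",
    "VOLUMETRIC_VARIABLES",
]

SATISFACTORY = "satisfactory"
UNSATISFACTORY = "unsatisfactory"


@dataclass
class StatResult:
    """One fitted comparison or regression.

    ``estimate`` is a mean difference (t tests) or an odds ratio (logistic);
    ``c_statistic`` is populated for logistic fits only. ``n`` holds the
    per-group sizes.
    """

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: tuple[int, ...]
    c_statistic: float | None = None
    converged: bool = True
    note: str = ""


def dichotomize(engel_class: str) -> str:
    """Engel class I (incl. IA/IB sub-tags) -> satisfactory; II-IV -> unsatisfactory."""
    cls = str(engel_class).strip().upper()
    if cls in {"I", "IA", "IB", "IC", "ID"}:
        return SATISFACTORY
    if cls in {"II", "III", "IV"}:
        return UNSATISFACTORY
    raise ValueError(f"unknown Engel class {engel_class!r}")


def paired_t(x: np.ndarray, y: np.ndarray, ci_level: float = 0.95) -> StatResult:
    """Paired-samples t test; estimate and CI are for the mean of x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    return StatResult(mean, mean - crit * se, mean + crit * se, float(p), (n,))


def independent_t(
    g1: np.ndarray, g2: np.ndarray, welch: bool = False, ci_level: float = 0.95
) -> StatResult:
    """Independent-samples t test; estimate and CI are for mean(g1) - mean(g2).

    Pooled-variance (Student) by default, Welch with ``welch=True``.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    diff = g1.mean() - g2.mean()
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        return StatResult(diff, diff, diff, p, (n1, n2), note="degenerate zero variance")
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    return StatResult(diff, diff - crit * se, diff + crit * se, float(p), (n1, n2))


def _rank_concordance(y: np.ndarray, x: np.ndarray) -> float:
    """C-statistic of the raw predictor: P(x_pos > x_neg) with tie credit 1/2."""
    pos = x[y == 1]
    neg = x[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins) / (pos.size * neg.size)


def logistic_single(y: np.ndarray, x: np.ndarray, ci_level: float = 0.95) -> StatResult:
    """Univariate logistic regression of a binary outcome on one predictor.

    Returns the odds ratio per unit of ``x`` with its Wald CI and p value
    and the C-statistic of the fitted probabilities. Complete separation is
    reported as a non-converged result carrying the rank C-statistic, not
    raised.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("outcome and predictor must have equal length")
    if y.size < 3:
        raise ValueError("need at least three subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n = (int((y == 1).sum()), int((y == 0).sum()))
    if np.ptp(x) == 0:
        # constant predictor: slope 0 by symmetry, no discrimination
        return StatResult(1.0, np.nan, np.nan, 1.0, n, c_statistic=0.5,
                          note="constant predictor")
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        for cat in (ConvergenceWarning, PerfectSeparationWarning, RuntimeWarning):
            warnings.filterwarnings("error", category=cat)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:  # perfect separation or non-convergence
            return StatResult(
                np.nan, np.nan, np.nan, np.nan, n,
                c_statistic=_rank_concordance(y, x), converged=False,
                note=f"non-convergent fit (possible separation): {type(exc).__name__}",
            )
    slope = fit.params[1]
    se = fit.bse[1]
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    auc = float(roc_auc_score(y, fit.predict(X)))
    return StatResult(
        float(np.exp(slope)),
        float(np.exp(slope - z * se)),
        float(np.exp(slope + z * se)),
        float(fit.pvalues[1]),
        n,
        c_statistic=auc,
    )


# (column suffix template, human-readable row label) for the five variable
# families analysed per VOI: tracer pre-surgical / resected abnormality
# volume, tracer percentage of non-resected abnormality, and the
# MRI-derived resected volume and percentage
VOLUMETRIC_VARIABLES: tuple[tuple[str, str], ...] = (
    ("fdg_{voi}_pre_mm3", "FDG pre-surgical volume"),
    ("fdg_{voi}_resected_mm3", "FDG resected volume"),
    ("fdg_{voi}_nonres_pct", "FDG percentage of non-resected abnormality"),
    ("fmz_{voi}_pre_mm3", "FMZ pre-surgical volume"),
    ("fmz_{voi}_resected_mm3", "FMZ resected volume"),
    ("fmz_{voi}_nonres_pct", "FMZ percentage of non-resected abnormality"),
    ("mri_{voi}_resected_mm3", "MRI-derived volume resected"),
    ("mri_{voi}_resected_pct", "MRI percentage of resected volume"),
)

_VOIS = ("ahph", "tl")
_TRACERS = ("fdg", "fmz")


@dataclass
class CohortReport:
    """The three report tables plus bookkeeping.

    ``pre_post``: per-VOI, per-tracer, per-subgroup pre/resected/post
    abnormality means with the paired test of the reduction.
    ``subgroup``: satisfactory vs unsatisfactory comparison of every
    volumetric variable (independent t).
    ``logistic``: univariate odds ratio and C-statistic per variable.
    """

    pre_post: pd.DataFrame
    subgroup: pd.DataFrame
    logistic: pd.DataFrame
    n_tests: int = 0
    notes: list[str] = field(default_factory=list)

    def to_csv_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pre_post.to_csv(outdir / "pre_post_abnormality.csv", index=False)
        self.subgroup.to_csv(outdir / "subgroup_comparisons.csv", index=False)
        self.logistic.to_csv(outdir / "logistic_models.csv", index=False)

    def to_markdown(self) -> str:
        parts = [
            "## Pre/post abnormality volumes by outcome subgroup",
            self.pre_post.to_markdown(index=False),
            "\n## Outcome subgroup comparisons (independent t)",
            self.subgroup.to_markdown(index=False),
            "\n## Univariate logistic models of class-I outcome",
            self.logistic.to_markdown(index=False),
            f"\n{self.n_tests} hypothesis tests performed; alpha = 0.05 two-sided, "
            "no multiple-testing correction.",
        ]
        return "\n".join(parts)


def _mean_sd(v: pd.Series) -> str:
    return f"{v.mean():.0f} ({v.std(ddof=1):.0f})"


def cohort_report(cohort: pd.DataFrame, welch: bool = False) -> CohortReport:
    """Assemble the full statistical report from a per-subject cohort table.

    Requires an ``engel_class`` column and the volumetric columns named by
    ``VOLUMETRIC_VARIABLES``; both outcome classes must be present. Group
    means of post-resection abnormality equal group mean pre minus group
    mean resected by linearity, which the report relies on when printing
    the post column.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    outcome = cohort["engel_class"].map(dichotomize)
    if outcome.nunique() < 2:
        raise ValueError("cohort contains a single outcome class; statistics undefined")
    groups = {
        SATISFACTORY: cohort[outcome == SATISFACTORY],
        UNSATISFACTORY: cohort[outcome == UNSATISFACTORY],
    }
    n_tests = 0

    pre_post_rows = []
    for voi in _VOIS:
        for tracer in _TRACERS:
            pre_c = f"{tracer}_{voi}_pre_mm3"
            res_c = f"{tracer}_{voi}_resected_mm3"
            for gname, g in groups.items():
                pre = g[pre_c].to_numpy(dtype=float)
                res = g[res_c].to_numpy(dtype=float)
                post = pre - res
                t = paired_t(pre, post)
                n_tests += 1
                pre_post_rows.append({
                    "voi": voi, "tracer": tracer.upper(), "outcome": gname,
                    "n": len(g),
                    "pre_mean_mm3": pre.mean(), "pre_sd_mm3": pre.std(ddof=1),
                    "resected_mean_mm3": res.mean(), "resected_sd_mm3": res.std(ddof=1),
                    "post_mean_mm3": post.mean(), "post_sd_mm3": post.std(ddof=1),
                    "reduction_ci_low": t.ci_low, "reduction_ci_high": t.ci_high,
                    "p_value": t.p_value,
                })

    subgroup_rows = []
    logistic_rows = []
    y = (outcome == SATISFACTORY).to_numpy(dtype=float)
    for voi in _VOIS:
        for template, label in VOLUMETRIC_VARIABLES:
            col = template.format(voi=voi)
            g1 = groups[SATISFACTORY][col].to_numpy(dtype=float)
            g2 = groups[UNSATISFACTORY][col].to_numpy(dtype=float)
            t = independent_t(g1, g2, welch=welch)
            n_tests += 1
            subgroup_rows.append({
                "voi": voi, "variable": label,
                "n_satisfactory": g1.size, "n_unsatisfactory": g2.size,
                "satisfactory_mean": g1.mean(), "satisfactory_sd": g1.std(ddof=1),
                "unsatisfactory_mean": g2.mean(), "unsatisfactory_sd": g2.std(ddof=1),
                "difference_mean": t.estimate,
                "ci_low": t.ci_low, "ci_high": t.ci_high, "p_value": t.p_value,
            })
            lr = logistic_single(y, cohort[col].to_numpy(dtype=float))
            n_tests += 1
            logistic_rows.append({
                "voi": voi, "variable": label,
                "odds_ratio": lr.estimate,
                "ci_low": lr.ci_low, "ci_high": lr.ci_high,
                "p_value": lr.p_value, "c_statistic": lr.c_statistic,
                "converged": lr.converged,
            })

    return CohortReport(
        pre_post=pd.DataFrame(pre_post_rows),
        subgroup=pd.DataFrame(subgroup_rows),
        logistic=pd.DataFrame(logistic_rows),
        n_tests=n_tests,
    )
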