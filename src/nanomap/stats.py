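"""Group-comparison ladder for condition summaries.

Two groups: Shapiro-Wilk normality check per group, an F-ratio gate for
equal variances (alpha 0.05), then a two-tailed Student t-test (similar
variances) or Welch t-test (different variances).  More than two groups:
one-way ANOVA with a Tukey HSD post-test.  Non-normal data are not
auto-switched to a nonparametric test; the parametric result is emitted
with the failed normality gate recorded on the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "TestReport", "compare_groups"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class TestReport:
    """Outcome of a group comparison with its gating decisions."""

    groups: list[GroupSummary]
    normality_p: dict[str, float]
    normality_ok: bool
    variances_equal: bool | None
    test_used: str  # "t" | "welch_t" | "anova_tukey"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    pairwise: pd.DataFrame | None = None
    variance_gate_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def _f_variance_gate(a: np.ndarray, b: np.ndarray, alpha: float) -> tuple[bool, float]:
    """Two-sided F test for equal variances; True means 'similar variances'."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return True, 1.0
    if vb == 0 or va == 0:
        return False, 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    p = float(min(p, 1.0))
    return bool(p > alpha), p


def compare_groups(samples: dict[str, np.ndarray], alpha: float = 0.05) -> TestReport:
    """Compare two or more groups with the parametric ladder.

    Parameters
    ----------
    samples:
        Mapping of group label to 1-D sample array; every group needs
        n >= 2 (n >= 3 for the normality gate to run).
    alpha:
        Significance level for every gate and the final verdict
        (default 0.05).
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in samples.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n={len(v)} < 2")

    warnings: list[str] = []
    normality_p: dict[str, float] = {}
    for k, v in arrays.items():
        if len(v) < 3:
            normality_p[k] = math.nan
            warnings.append(f"group {k!r}: n < 3, normality gate skipped")
        elif np.ptp(v) == 0:
            normality_p[k] = 0.0
            warnings.append(f"group {k!r}: constant sample, treated as non-normal")
        else:
            normality_p[k] = float(sps.shapiro(v).pvalue)
    normality_ok = all((math.isnan(p) or p > alpha) for p in normality_p.values())
    if not normality_ok:
        warnings.append("normality gate failed; parametric result emitted with flag")

    groups = [
        GroupSummary(
            k, len(v), float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else math.nan
        )
        for k, v in arrays.items()
    ]

    labels = list(arrays)
    if len(arrays) == 2:
        a, b = arrays[labels[0]], arrays[labels[1]]
        if np.array_equal(a, b):
            # identical samples: no difference by construction
            equal_var, gate_p = True, 1.0
            stat, p = 0.0, 1.0
            test_used = "t"
        else:
            equal_var, gate_p = _f_variance_gate(a, b, alpha)
            test_used = "t" if equal_var else "welch_t"
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            stat, p = float(res.statistic), float(res.pvalue)
        return TestReport(
            groups=groups,
            normality_p=normality_p,
            normality_ok=normality_ok,
            variances_equal=equal_var,
            variance_gate_p=gate_p,
            test_used=test_used,
            statistic=stat,
            p_value=p,
            alpha=alpha,
            significant=p < alpha,
            warnings=warnings,
        )

    # > 2 groups: one-way ANOVA with Tukey HSD post-test
    values = [arrays[k] for k in labels]
    res = sps.f_oneway(*values)
    tukey = sps.tukey_hsd(*values)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(values[i].mean() - values[j].mean()),
                    "p_value": float(tukey.pvalue[i, j]),
                    "significant": bool(tukey.pvalue[i, j] < alpha),
                }
            )
    return TestReport(
        groups=groups,
        normality_p=normality_p,
        normality_ok=normality_ok,
        variances_equal=None,
        test_used="anova_tukey",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        significant=float(res.pvalue) < alpha,
        pairwise=pd.DataFrame(rows),
        warnings=warnings,
    )
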