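"""Two-sample F-test and pooled t-test for measured-vs-predicted validation.

After calibrating a model, the standard external check compares the 50
measured reference values with the 50 model predictions: the F-test asks
whether the two dispersions differ (variance homogeneity), the pooled
two-sample t-test whether there is a systematic bias in the means. The
report block mirrors the spreadsheet-style layout common in chemometrics
reporting: group means, sample variances (n-1 denominator), the F statistic
with its one-tailed p and critical value, then the pooled ("merged")
variance, t statistic, one- and two-tailed p-values and critical values.

Conventions: the measured group's variance goes in the F numerator (not
larger-on-top), and the t-test pools variances (equal-variance form), both
matching the reporting convention this package reproduces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TwoSampleTestReport",
    "two_sample_f_test",
    "two_sample_t_test_pooled",
    "two_sample_report",
    "distribution_critical",
]


@dataclass
class TwoSampleTestReport:
    """Full F-test + pooled t-test block for one (measured, predicted) pair."""

    mean_a: float
    mean_b: float
    var_a: float  # sample variance, ddof=1
    var_b: float
    n_a: int
    n_b: int
    alpha: float
    # F-test block
    f_stat: float
    f_p_one_tailed: float
    f_critical_one_tailed: float
    # t-test block
    pooled_variance: float
    assumed_mean_difference: float
    t_stat: float
    t_df: int
    t_p_one_tailed: float
    t_p_two_tailed: float
    t_critical_one_tailed: float
    t_critical_two_tailed: float

    @property
    def f_df(self) -> tuple[int, int]:
        return (self.n_a - 1, self.n_b - 1)

    def recompute(self) -> "TwoSampleTestReport":
        """Regenerate every statistic from the stored raw summaries
        (means, variances, n); used as a self-consistency invariant."""
        return _report_from_summaries(
            self.mean_a, self.var_a, self.n_a,
            self.mean_b, self.var_b, self.n_b,
            self.alpha,
        )

    def max_deviation(self, other: "TwoSampleTestReport") -> float:
        fields = [
            "f_stat", "f_p_one_tailed", "f_critical_one_tailed",
            "pooled_variance", "t_stat", "t_p_one_tailed", "t_p_two_tailed",
            "t_critical_one_tailed", "t_critical_two_tailed",
        ]
        return max(abs(getattr(self, f) - getattr(other, f)) for f in fields)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def render_table(self, label_a: str = "Measured", label_b: str = "Predicted") -> str:
        """Two-column text block with display rounding (1 dp summaries,
        4 dp statistics); full precision is kept in the JSON form."""
        rows = [
            ("Item", label_a, label_b),
            ("Average", f"{self.mean_a:.1f}", f"{self.mean_b:.1f}"),
            ("Variance", f"{self.var_a:.1f}", f"{self.var_b:.1f}"),
            ("Observed value", str(self.n_a), str(self.n_b)),
            ("df", str(self.n_a - 1), str(self.n_b - 1)),
            ("F", f"{self.f_stat:.4f}", ""),
            ("P (F<=f) one-tailed", f"{self.f_p_one_tailed:.4f}", ""),
            ("F one-tailed critical value", f"{self.f_critical_one_tailed:.4f}", ""),
            ("Merger of variance", f"{self.pooled_variance:.1f}", ""),
            ("Assumed mean difference", f"{self.assumed_mean_difference:g}", ""),
            ("df (pooled)", str(self.t_df), ""),
            ("t Stat", f"{self.t_stat:.4f}", ""),
            ("P (T<=t) one-tailed", f"{self.t_p_one_tailed:.4f}", ""),
            ("t one-tailed critical value", f"{self.t_critical_one_tailed:.4f}", ""),
            ("P (T<=t) two-tailed", f"{self.t_p_two_tailed:.4f}", ""),
            ("t two-tailed critical value", f"{self.t_critical_two_tailed:.4f}", ""),
        ]
        width = max(len(r[0]) for r in rows) + 2
        return "\n".join(f"{r[0]:<{width}}{r[1]:>12}{r[2]:>12}" for r in rows) + "\n"


def _summaries(x: np.ndarray) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("each group needs at least 2 values")
    return float(x.mean()), float(x.var(ddof=1)), int(x.size)


def _f_block(var_a, n_a, var_b, n_b, alpha):
    if var_b <= 0:
        raise ValueError("zero variance in the F denominator group")
    F = var_a / var_b
    df1, df2 = n_a - 1, n_b - 1
    if F >= 1:
        p = float(_stats.f.sf(F, df1, df2))
    else:
        p = float(_stats.f.cdf(F, df1, df2))
    crit = float(_stats.f.isf(alpha, df1, df2))
    return F, p, crit


def _t_block(mean_a, var_a, n_a, mean_b, var_b, n_b, alpha):
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p_one = float(_stats.t.sf(abs(t), df))
    return sp2, t, df, p_one, 2 * p_one, float(_stats.t.isf(alpha, df)), float(
        _stats.t.isf(alpha / 2, df)
    )


def _report_from_summaries(mean_a, var_a, n_a, mean_b, var_b, n_b, alpha):
    F, f_p, f_crit = _f_block(var_a, n_a, var_b, n_b, alpha)
    sp2, t, df, p1, p2, c1, c2 = _t_block(mean_a, var_a, n_a, mean_b, var_b, n_b, alpha)
    return TwoSampleTestReport(
        mean_a=mean_a, mean_b=mean_b, var_a=var_a, var_b=var_b,
        n_a=n_a, n_b=n_b, alpha=alpha,
        f_stat=F, f_p_one_tailed=f_p, f_critical_one_tailed=f_crit,
        pooled_variance=sp2, assumed_mean_difference=0.0,
        t_stat=t, t_df=df, t_p_one_tailed=p1, t_p_two_tailed=p2,
        t_critical_one_tailed=c1, t_critical_two_tailed=c2,
    )


def two_sample_report(a, b, alpha: float = 0.05) -> TwoSampleTestReport:
    """Full F + pooled-t report for measured group ``a`` vs predicted ``b``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ma, va, na = _summaries(a)
    mb, vb, nb = _summaries(b)
    return _report_from_summaries(ma, va, na, mb, vb, nb, alpha)


def two_sample_f_test(a, b, alpha: float = 0.05) -> dict:
    """Variance-ratio F-test with the measured group in the numerator.

    Returns the F statistic, its one-tailed p-value (upper tail when F >= 1,
    lower tail otherwise) and the upper-alpha critical value of
    F(n_a-1, n_b-1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ma, va, na = _summaries(a)
    mb, vb, nb = _summaries(b)
    F, p, crit = _f_block(va, na, vb, nb, alpha)
    return {
        "mean_a": ma, "mean_b": mb, "var_a": va, "var_b": vb,
        "n_a": na, "n_b": nb, "df": (na - 1, nb - 1),
        "F": F, "p_one_tailed": p, "critical_one_tailed": crit, "alpha": alpha,
    }


def two_sample_t_test_pooled(a, b, alpha: float = 0.05) -> dict:
    """Equal-variance two-sample t-test (pooled variance), zero assumed
    mean difference."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ma, va, na = _summaries(a)
    mb, vb, nb = _summaries(b)
    sp2, t, df, p1, p2, c1, c2 = _t_block(ma, va, na, mb, vb, nb, alpha)
    return {
        "mean_a": ma, "mean_b": mb, "var_a": va, "var_b": vb,
        "n_a": na, "n_b": nb, "pooled_variance": sp2, "df": df,
        "t": t, "p_one_tailed": p1, "p_two_tailed": p2,
        "critical_one_tailed": c1, "critical_two_tailed": c2, "alpha": alpha,
    }


def distribution_critical(dist: str, alpha: float, df, tails: int = 1) -> float:
    """Upper critical value of the F or t distribution.

    For ``dist="f"``, ``df`` is a (df1, df2) pair and ``tails`` must be 1.
    For ``dist="t"``, ``tails=2`` returns the two-tailed critical value
    (upper alpha/2 quantile); ``df=inf`` gives the normal limit.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if dist == "f":
        if tails != 1:
            raise ValueError("the F critical value here is one-tailed")
        df1, df2 = df
        if df1 <= 0 or df2 <= 0:
            raise ValueError("df must be > 0")
        return float(_stats.f.isf(alpha, df1, df2))
    if dist == "t":
        if df != math.inf and df <= 0:
            raise ValueError("df must be > 0")
        a = alpha / 2 if tails == 2 else alpha
        if df == math.inf:
            return float(_stats.norm.isf(a))
        return float(_stats.t.isf(a, df))
    raise ValueError(f"unknown distribution {dist!r}")
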