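"""Method-validation statistics.

Precision/accuracy (CV%, relative error%), standard-addition recovery, and
method comparison against a reference assay by Student's paired t-test and
the variance-ratio F-test.  Sample SDs use the n−1 denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PrecisionResult",
    "ComparisonResult",
    "precision_accuracy",
    "recovery_standard_addition",
    "paired_t_test",
    "variance_ratio_f_test",
    "compare_methods",
    "t_critical",
    "f_critical",
    "precision_table",
    "comparison_table",
]

NO_DIFFERENCE = "no_significant_difference"
DIFFERENCE = "significant_difference"


@dataclass(frozen=True)
class PrecisionResult:
    """Within-day or between-day precision and accuracy at one level.

    cv_percent = 100·SD/mean of the found values; error_percent =
    100·(found mean − nominal)/nominal.
    """

    nominal: float
    found_mean: float
    found_sd: float
    cv_percent: float
    error_percent: float
    n: int
    scope: str = "within_day"


@dataclass(frozen=True)
class ComparisonResult:
    """Paired-t and/or variance-ratio F comparison of two methods.

    ``conclusion`` is ``no_significant_difference`` iff every computed
    statistic stays below its critical value (|t| < t_crit and F < f_crit).
    F uses the fixed a-over-b convention (test method variance over reference
    method variance), so values below 1 are meaningful and reported as-is.
    """

    alpha: float
    t_stat: float | None = None
    t_crit: float | None = None
    df_t: int | None = None
    f_stat: float | None = None
    f_crit: float | None = None
    df_f_num: int | None = None
    df_f_den: int | None = None
    degenerate: bool = False

    @property
    def conclusion(self) -> str:
        if self.t_stat is not None and not abs(self.t_stat) < self.t_crit:
            return DIFFERENCE
        if self.f_stat is not None and not self.f_stat < self.f_crit:
            return DIFFERENCE
        return NO_DIFFERENCE


def t_critical(alpha: float, df: int) -> float:
    """Two-sided Student's t critical value at significance ``alpha``."""
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(stats.t.ppf(1 - alpha / 2, df))


def f_critical(alpha: float, df_num: int, df_den: int) -> float:
    """Upper-tail F critical value at significance ``alpha``."""
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be at least 1")
    return float(stats.f.ppf(1 - alpha, df_num, df_den))


def precision_accuracy(
    found: Sequence[float], nominal: float, scope: str = "within_day"
) -> PrecisionResult:
    """CV% and relative error% of replicate determinations at one level."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    x = np.asarray(list(found), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicate determinations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return PrecisionResult(
        nominal=float(nominal),
        found_mean=mean,
        found_sd=sd,
        cv_percent=100.0 * sd / mean if mean != 0 else float("inf"),
        error_percent=100.0 * (mean - nominal) / nominal,
        n=int(x.size),
        scope=scope,
    )


def recovery_standard_addition(found_spiked: float, found_base: float, added: float) -> float:
    """Percent of a known spike recovered on top of the sample's own content."""
    if added <= 0:
        raise ValueError("added amount must be positive")
    return 100.0 * (found_spiked - found_base) / added


def paired_t_test(
    method_a: Sequence[float], method_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Student's paired t-test on matched determinations of two methods.

    t = mean(d) / (SD(d)/√n) on the paired differences, df = n − 1, compared
    against the two-sided critical value.  Zero-variance differences with a
    nonzero mean yield an infinite t flagged ``degenerate``.
    """
    a = np.asarray(list(method_a), dtype=float)
    b = np.asarray(list(method_b), dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length samples of at least 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    degenerate = False
    if sd == 0:
        if d.mean() == 0:
            t = 0.0
        else:
            t = math.copysign(math.inf, d.mean())
            degenerate = True
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    return ComparisonResult(
        alpha=alpha, t_stat=t, t_crit=t_critical(alpha, n - 1), df_t=n - 1, degenerate=degenerate
    )


def variance_ratio_f_test(
    method_a: Sequence[float], method_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Variance-ratio F-test with the fixed a/b convention.

    F = s_a²/s_b² (test over reference), df (n_a−1, n_b−1), judged against
    the upper critical value.  The ratio is deliberately not folded to
    max/min, so sub-unity F values are reported as such.
    """
    a = np.asarray(list(method_a), dtype=float)
    b = np.asarray(list(method_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("reference method variance is zero; F is undefined")
    f = float(a.var(ddof=1) / vb)
    return ComparisonResult(
        alpha=alpha,
        f_stat=f,
        f_crit=f_critical(alpha, a.size - 1, b.size - 1),
        df_f_num=a.size - 1,
        df_f_den=b.size - 1,
    )


def compare_methods(
    method_a: Sequence[float], method_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Combined paired-t and F comparison of a test method against a reference."""
    t_part = paired_t_test(method_a, method_b, alpha)
    f_part = variance_ratio_f_test(method_a, method_b, alpha)
    return ComparisonResult(
        alpha=alpha,
        t_stat=t_part.t_stat,
        t_crit=t_part.t_crit,
        df_t=t_part.df_t,
        f_stat=f_part.f_stat,
        f_crit=f_part.f_crit,
        df_f_num=f_part.df_f_num,
        df_f_den=f_part.df_f_den,
        degenerate=t_part.degenerate,
    )


# ---------------------------------------------------------------------------
# Report tables


def precision_table(results: Sequence[PrecisionResult], compound_id: str = ""):
    """Accuracy/precision rows (one per level and scope) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound": compound_id,
                "scope": r.scope,
                "added_ug_per_ml": r.nominal,
                "found_ug_per_ml": round(r.found_mean, 2),
                "found_sd": round(r.found_sd, 2),
                "cv_percent": round(r.cv_percent, 2),
                "error_percent": round(r.error_percent, 2),
                "n": r.n,
            }
            for r in results
        ]
    )


def comparison_table(results: dict):
    """Method-comparison rows (compound → ComparisonResult) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound": cid,
                "t": round(r.t_stat, 3) if r.t_stat is not None else None,
                "F": round(r.f_stat, 3) if r.f_stat is not None else None,
                "t_critical": round(r.t_crit, 3) if r.t_crit is not None else None,
                "F_critical": round(r.f_crit, 2) if r.f_crit is not None else None,
                "conclusion": r.conclusion,
            }
            for cid, r in results.items()
        ]
    )
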