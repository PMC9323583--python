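"""Agreement statistics: single-measure intraclass correlation with exact
F-based 95% confidence intervals, coefficient of variation, Bland-Altman
limits of agreement, paired t-test, Shapiro-Wilk normality check, and the
Cicchetti reliability classification.

The ICC forms follow the Shrout-Fleiss single-measure definitions computed
from ANOVA mean squares of the complete two-way subject x rater layout:

* ICC(1,1) - one-way random effects,
* ICC(2,1) - two-way random effects, absolute agreement,
* ICC(3,1) - two-way mixed effects, consistency.

Confidence intervals use the exact F bounds for ICC(1,1)/ICC(3,1) and the
Satterthwaite-approximate F bounds for ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError

ICC_MODELS = ("ICC_1_1", "ICC_2_1", "ICC_3_1")
_MODEL_ALIASES = {
    "icc1": "ICC_1_1", "icc2": "ICC_2_1", "icc3": "ICC_3_1",
    "ICC_1_1": "ICC_1_1", "ICC_2_1": "ICC_2_1", "ICC_3_1": "ICC_3_1",
    "1,1": "ICC_1_1", "2,1": "ICC_2_1", "3,1": "ICC_3_1",
}


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    mean_squares: dict


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: list  # (mean, difference) per subject


@dataclass
class CVResult:
    cv_percent: float
    aggregation: str


def pivot_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format measurement table to subjects x raters.

    Requires a complete design: every subject measured by every rater
    exactly once.
    """
    required = {"participant_id", "rater_id", "value"}
    if not required.issubset(table.columns):
        raise InputError(f"table must have columns {sorted(required)}")
    wide = table.pivot(index="participant_id", columns="rater_id",
                       values="value")
    if wide.isna().any().any():
        raise InputError("incomplete design: missing subject x rater cells")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise InputError("need at least 2 subjects and 2 raters")
    return wide


def _anova_mean_squares(y: np.ndarray) -> dict:
    """Two-way crossed ANOVA mean squares for an n x k matrix."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))  # one-way within-subject MS
    return {"between_subjects": msr, "between_raters": msc,
            "error": mse, "within_subjects": msw}


def icc(table, model: str = "ICC_2_1", alpha: float = 0.05) -> ICCResult:
    """Single-measure ICC with a 95% CI from a complete two-way table.

    ``table`` is either a long-format DataFrame (participant_id, rater_id,
    value) or an n x k array of measurements.
    """
    if model not in _MODEL_ALIASES:
        raise InputError(f"unknown ICC model {model!r}; use one of "
                         f"{sorted(set(_MODEL_ALIASES))}")
    model = _MODEL_ALIASES[model]
    if isinstance(table, pd.DataFrame) and "value" in table.columns:
        y = pivot_table(table).to_numpy(dtype=float)
    else:
        y = np.asarray(table, dtype=float)
        if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
            raise InputError("measurement matrix must be at least 2 x 2")
        if np.isnan(y).any():
            raise InputError("incomplete design: missing cells")
    n, k = y.shape
    if np.allclose(y, y.flat[0]):
        raise DegenerateInputError("zero total variance in measurements")

    ms = _anova_mean_squares(y)
    msr, msc, mse, msw = (ms["between_subjects"], ms["between_raters"],
                          ms["error"], ms["within_subjects"])

    if model == "ICC_1_1":
        est = (msr - msw) / (msr + (k - 1) * msw)
        if msw == 0.0:  # perfect agreement: estimate is exact
            low = high = est
        else:
            f = msr / msw
            df1, df2 = n - 1, n * (k - 1)
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            low = (fl - 1) / (fl + k - 1)
            high = (fu - 1) / (fu + k - 1)
    elif model == "ICC_3_1":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:  # perfect consistency
            low = high = est
        else:
            f = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            low = (fl - 1) / (fl + k - 1)
            high = (fu - 1) / (fu + k - 1)
    else:  # ICC_2_1
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if mse == 0.0:  # residual-free table: estimate is exact
            low = high = est
        else:
            fj = msc / mse
            r = max(est, 0.0)
            vn = (k - 1) * (n - 1) * (k * r * fj + n * (1 + (k - 1) * r)
                                      - k * r) ** 2
            vd = ((n - 1) * k ** 2 * r ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * r) - k * r) ** 2)
            v = vn / vd
            f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
            low = (n * (msr - f_low * mse)
                   / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
            high = (n * (f_up * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_up * msr))

    low = min(low, est)
    high = max(high, est)
    return ICCResult(estimate=float(est), ci_low=float(low),
                     ci_high=float(high), model=model, mean_squares=ms)


def cv(values_per_subject: Iterable[Sequence[float]],
       aggregation: str = "pooled_per_subject_mean") -> CVResult:
    """Coefficient of variation, SD / mean x 100.

    ``pooled_per_subject_mean``: each subject's CV across their repeats,
    averaged over subjects.  ``overall``: CV of the flattened series.
    """
    groups = [np.asarray(g, dtype=float) for g in values_per_subject]
    if aggregation not in ("pooled_per_subject_mean", "overall"):
        raise InputError(f"unknown aggregation {aggregation!r}")
    if not groups:
        raise InputError("no measurements supplied")
    if aggregation == "overall":
        flat = np.concatenate(groups)
        if flat.size < 2:
            raise InputError("need at least 2 values overall")
        m = flat.mean()
        if m <= 0:
            raise InputError("mean must be positive for CV")
        return CVResult(cv_percent=float(flat.std(ddof=1) / m * 100.0),
                        aggregation=aggregation)
    per = []
    for g in groups:
        if g.size < 2:
            raise InputError("each subject needs at least 2 repeats")
        m = g.mean()
        if m <= 0:
            raise InputError("subject mean must be positive for CV")
        per.append(g.std(ddof=1) / m * 100.0)
    return CVResult(cv_percent=float(np.mean(per)), aggregation=aggregation)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and 95% limits of agreement (bias +/- 1.96 sample SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D series of equal length")
    if x.size < 3:
        raise InputError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        pairs=list(zip(((x + y) / 2.0).tolist(), d.tolist())),
    )


def paired_t(x, y) -> tuple[float, float]:
    """Paired Student t-test; returns (t statistic, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D series of equal length")
    if x.size < 2:
        raise InputError("need at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0.0:
        raise DegenerateInputError("zero variance in paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise InputError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0.0:
        raise DegenerateInputError("constant series")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def cicchetti_label(icc_estimate: float) -> str:
    """Clinical-significance band of a reliability coefficient."""
    if not -1.0 <= icc_estimate <= 1.0:
        raise InputError("ICC estimate must be in [-1, 1]")
    if icc_estimate < 0.40:
        return "poor"
    if icc_estimate < 0.60:
        return "fair"
    if icc_estimate < 0.75:
        return "good"
    return "excellent"


def summarize(values, decimals: int = 3) -> dict:
    """Descriptive summary with a "mean +/- SD (range)" rendering."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 values")
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    lo, hi = float(v.min()), float(v.max())

    def fmt(x: float) -> str:
        return f"{round(x, decimals):g}"

    return {
        "mean": mean, "sd": sd, "min": lo, "max": hi,
        "formatted": f"{fmt(mean)} ± {fmt(sd)} ({fmt(lo)}–{fmt(hi)})",
    }


def format_proportion(count: int, total: int) -> tuple[float, str]:
    """Categorical "n (%)" rendering; percentage to two decimals."""
    if total <= 0 or count < 0 or count > total:
        raise InputError("need 0 <= count <= total with total > 0")
    pct = round(100.0 * count / total, 2)
    return pct, f"{count} ({pct:.2f})"
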