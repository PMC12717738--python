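"""Method-agreement statistics for paired ECG measurements.

The validation suite used to compare two measurement arms (two readers, two
readings, or TAM vs TCM):

* Bland-Altman bias, SD of differences, 1.96-SD limits of agreement and a
  proportional-bias test (differences regressed on pair means),
* repeatability coefficient RC = 1.96 x SD of paired differences,
* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation with its F-based 95% confidence interval
  (McGraw & Wong's ICC(A,1) interval),
* a clustered Bland-Altman variant that decomposes the difference variance
  into between-subject, between-timepoint and residual components by the
  method of moments, widening the limits of agreement accordingly,
* TOST non-inferiority on paired differences with a ±5 ms margin and the
  regulatory requirement that the 90% CI upper bound stay below 10 ms,
* Benjamini-Hochberg FDR adjustment for secondary endpoints,
* a table-level driver producing one agreement summary per ECG parameter.

Differences are oriented as (first-named arm − second-named arm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "ComparisonResult",
    "AgreementError",
    "bland_altman",
    "limits_of_agreement",
    "repeatability_coefficient",
    "icc_2_1",
    "clustered_bland_altman",
    "tost_ni",
    "bh_fdr",
    "compare_tables",
    "bland_altman_plot",
    "AGREEMENT_PARAMETERS",
]

#: Parameters summarized by compare_tables, in report (column) order.
AGREEMENT_PARAMETERS = ("hr_bpm", "pr_ms", "qrs_ms", "qtcf_ms",
                       "soko_v5_uv", "soko_v6_uv")

Z_LOA = 1.96  # normal quantile used for limits of agreement and RC


class AgreementError(ValueError):
    """Raised for degenerate or malformed paired inputs."""


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements of one parameter from two arms (same units).

    Pairs with a missing side must be dropped before construction; the
    caller records how many were dropped (``n_dropped``).
    """

    x: np.ndarray
    y: np.ndarray
    parameter: str = ""
    subject_id: tuple = ()
    timepoint_id: tuple = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise AgreementError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise AgreementError(f"need >= 2 pairs, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise AgreementError("paired values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y

    @property
    def means(self) -> np.ndarray:
        return (self.x + self.y) / 2.0


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement summary for one parameter (Table-style row)."""

    parameter: str
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    rc: float
    icc: float | None
    icc_ci: tuple[float, float] | None
    prop_bias_slope: float | None
    prop_bias_p: float | None
    tost_ci90: tuple[float, float]
    ni_pass_5ms: bool
    e14_pass_10ms: bool
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        lo, hi = (self.icc_ci if self.icc_ci is not None else (None, None))
        return {
            "parameter": self.parameter,
            "n": self.n,
            "icc": None if self.icc is None else round(self.icc, 3),
            "icc_ci_low": None if lo is None else round(lo, 3),
            "icc_ci_high": None if hi is None else round(hi, 3),
            "bias": round(self.bias, 2),
            "sd_bias": round(self.sd_diff, 2),
            "loa_upper": round(self.loa_upper, 2),
            "loa_lower": round(self.loa_lower, 2),
            "rc": round(self.rc, 2),
            "prop_bias_slope": None if self.prop_bias_slope is None
            else round(self.prop_bias_slope, 4),
            "prop_bias_p": None if self.prop_bias_p is None
            else round(self.prop_bias_p, 4),
            "tost_ci90_low": round(self.tost_ci90[0], 2),
            "tost_ci90_high": round(self.tost_ci90[1], 2),
            "ni_pass_5ms": self.ni_pass_5ms,
            "e14_pass_10ms": self.e14_pass_10ms,
        }


def bland_altman(series: PairedSeries) -> dict:
    """Bias, SD of differences (n−1 denominator) and proportional-bias test.

    The proportional-bias slope comes from ordinary least squares of the
    differences on the pair means, with a two-sided t-test on the slope.
    With constant differences (zero variance) the regression is skipped and
    flagged.  Requires n >= 3 for the regression, n >= 2 for bias/SD.
    """
    d = series.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    out = {"n": series.n, "bias": bias, "sd_diff": sd,
           "prop_bias_slope": None, "prop_bias_p": None, "flags": []}
    if sd == 0.0:
        out["flags"].append("constant_differences")
        out["prop_bias_slope"] = 0.0
        return out
    if series.n >= 3 and np.std(series.means) > 0:
        res = stats.linregress(series.means, d)
        out["prop_bias_slope"] = float(res.slope)
        out["prop_bias_p"] = float(res.pvalue)
    else:
        out["flags"].append("proportional_bias_untestable")
    return out


def limits_of_agreement(bias: float, sd_diff: float) -> tuple[float, float]:
    """(bias − 1.96·SD, bias + 1.96·SD)."""
    if sd_diff < 0:
        raise AgreementError(f"sd_diff must be >= 0, got {sd_diff}")
    return bias - Z_LOA * sd_diff, bias + Z_LOA * sd_diff


def repeatability_coefficient(sd_diff: float) -> float:
    """RC = 1.96 × SD of paired within-method differences."""
    if sd_diff < 0:
        raise AgreementError(f"sd_diff must be >= 0, got {sd_diff}")
    return Z_LOA * sd_diff


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its F-based confidence interval.

    ``ratings`` is a complete subjects × raters table (n >= 3 rows,
    k >= 2 columns).  The point estimate is the two-way random-effects,
    absolute-agreement, single-measure ICC

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with MSR/MSC/MSE the rows/columns/error mean squares of the two-way
    ANOVA.  The CI follows McGraw & Wong's ICC(A,1) construction using the
    Satterthwaite degrees of freedom.  A table with zero total variance has
    no defined ICC and raises ``AgreementError``.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise AgreementError("ratings must be a 2-D subjects × raters table")
    if not np.all(np.isfinite(table)):
        raise AgreementError("ratings table must be complete (no missing cells)")
    n, k = table.shape
    if n < 3 or k < 2:
        raise AgreementError(f"need >= 3 subjects and >= 2 raters, got {n}×{k}")

    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_total == 0 or denom == 0:
        raise AgreementError("ICC undefined: zero total variance in the table")
    icc = float((msr - mse) / denom)

    # --- McGraw & Wong ICC(A,1) F-based interval ---
    if mse == 0:
        # perfect within-subject agreement: the interval degenerates
        return icc, (icc, icc)
    fj = msc / mse
    df_e = (n - 1) * (k - 1)
    # Satterthwaite df for the denominator
    vn = df_e * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    if np.isfinite(f_u):
        lower = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    else:  # limit of the expression as the F quantile diverges (tiny df)
        lower = -n * mse / (k * msc + (k * n - k - n) * mse)
    if np.isfinite(f_l):
        upper = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        upper = 1.0
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return icc, (lower, upper)


def clustered_bland_altman(
    differences: Sequence[float],
    subject_id: Sequence,
    timepoint_id: Sequence | None = None,
) -> dict:
    """Bland-Altman with variance components for clustered differences.

    Method-of-moments decomposition of the paired differences into
    between-subject, between-timepoint and residual variance (negative
    moment estimates truncated at zero); the limits of agreement use the
    total SD (root of the summed components).  With a single subject the
    computation falls back to the simple Bland-Altman SD with a warning.
    """
    d = np.asarray(differences, dtype=float)
    subj = np.asarray(subject_id)
    if d.size != subj.size:
        raise AgreementError("differences and subject_id must align")
    if d.size < 2:
        raise AgreementError("need >= 2 differences")
    bias = float(np.mean(d))
    subjects = np.unique(subj)

    if subjects.size < 2:
        warnings.warn("single subject: falling back to simple Bland-Altman")
        sd = float(np.std(d, ddof=1))
        lo, hi = limits_of_agreement(bias, sd)
        return {"bias": bias, "sd_total": sd, "loa_lower": lo, "loa_upper": hi,
                "var_subject": 0.0, "var_timepoint": 0.0,
                "var_residual": sd**2, "fallback_simple": True}

    resid = d - bias
    # between-subject component from subject means (MoM, unbalanced-safe)
    groups = [resid[subj == s] for s in subjects]
    n_i = np.array([g.size for g in groups], dtype=float)
    means_i = np.array([g.mean() for g in groups])
    # pooled within-subject variance
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_within = int(np.sum(n_i - 1))
    var_within = within_ss / df_within if df_within > 0 else 0.0
    # subject component: var of subject means minus its sampling noise
    var_means = float(np.var(means_i, ddof=1))
    n_harm = subjects.size / float(np.sum(1.0 / n_i))
    var_subject = max(var_means - var_within / n_harm, 0.0)

    var_timepoint = 0.0
    var_residual = var_within
    if timepoint_id is not None:
        tp = np.asarray(timepoint_id)
        if tp.size != d.size:
            raise AgreementError("timepoint_id must align with differences")
        times = np.unique(tp)
        if times.size >= 2:
            # timepoint component from timepoint means of subject-centred
            # residuals, with its own sampling-noise correction
            centred = resid.copy()
            for s, g_mean in zip(subjects, means_i):
                centred[subj == s] -= g_mean
            means_t = np.array([centred[tp == t].mean() for t in times])
            m_j = np.array([(tp == t).sum() for t in times], dtype=float)
            m_harm = times.size / float(np.sum(1.0 / m_j))
            var_t_means = float(np.var(means_t, ddof=1))
            var_timepoint = max(var_t_means - var_within / m_harm, 0.0)
            var_residual = max(var_within - var_timepoint, 0.0)

    sd_total = float(np.sqrt(var_subject + var_timepoint + var_residual))
    lo, hi = limits_of_agreement(bias, sd_total)
    return {"bias": bias, "sd_total": sd_total, "loa_lower": lo,
            "loa_upper": hi, "var_subject": var_subject,
            "var_timepoint": var_timepoint, "var_residual": var_residual,
            "fallback_simple": False}


def tost_ni(
    differences: Sequence[float],
    margin: float = 5.0,
    alpha: float = 0.05,
    e14_bound: float = 10.0,
) -> dict:
    """Two one-sided tests for equivalence of paired differences.

    The 90% CI is mean ± t(1−alpha, n−1)·SE.  ``ni_pass_5ms`` requires the
    CI to lie entirely inside (−margin, +margin); ``e14_pass_10ms`` requires
    the CI upper bound below ``e14_bound``.  With zero SD the CI collapses
    to the mean and the verdicts are taken from the point value (flagged).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise AgreementError(f"need >= 2 differences, got {d.size}")
    if margin <= 0:
        raise AgreementError("margin must be > 0")
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    flags = []
    if sd == 0.0:
        ci = (mean, mean)
        p_lower = 0.0 if mean > -margin else 1.0
        p_upper = 0.0 if mean < margin else 1.0
        flags.append("degenerate_zero_sd")
    else:
        se = sd / np.sqrt(n)
        t_crit = stats.t.ppf(1 - alpha, n - 1)
        ci = (mean - t_crit * se, mean + t_crit * se)
        # H0a: mu <= -margin  vs  H1a: mu > -margin
        p_lower = float(stats.t.sf((mean + margin) / se, n - 1))
        # H0b: mu >= +margin  vs  H1b: mu < +margin
        p_upper = float(stats.t.cdf((mean - margin) / se, n - 1))
    ni_pass = (-margin < ci[0]) and (ci[1] < margin)
    return {
        "n": n, "mean": mean, "sd": sd,
        "ci90_lower": float(ci[0]), "ci90_upper": float(ci[1]),
        "p_lower": p_lower, "p_upper": p_upper,
        "tost_p": max(p_lower, p_upper),
        "ni_pass_5ms": bool(ni_pass),
        "e14_pass_10ms": bool(ci[1] < e14_bound),
        "flags": flags,
    }


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AgreementError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _compare_series(series: PairedSeries, margin: float = 5.0) -> ComparisonResult:
    ba = bland_altman(series)
    lo, hi = limits_of_agreement(ba["bias"], ba["sd_diff"])
    rc = repeatability_coefficient(ba["sd_diff"])
    try:
        icc, ci = icc_2_1(np.column_stack([series.x, series.y]))
    except AgreementError:
        icc, ci = None, None
        ba["flags"].append("icc_undefined")
    tost = tost_ni(series.differences, margin=margin)
    return ComparisonResult(
        parameter=series.parameter, n=series.n,
        bias=ba["bias"], sd_diff=ba["sd_diff"],
        loa_lower=lo, loa_upper=hi, rc=rc,
        icc=icc, icc_ci=ci,
        prop_bias_slope=ba["prop_bias_slope"], prop_bias_p=ba["prop_bias_p"],
        tost_ci90=(tost["ci90_lower"], tost["ci90_upper"]),
        ni_pass_5ms=tost["ni_pass_5ms"], e14_pass_10ms=tost["e14_pass_10ms"],
        flags=tuple(ba["flags"]) + tuple(tost["flags"]),
    )


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    keys: Sequence[str] = ("subject_id", "visit_label"),
    parameters: Sequence[str] = AGREEMENT_PARAMETERS,
    margin: float = 5.0,
) -> dict[str, ComparisonResult]:
    """Inner-join two measurement tables on ``keys`` and summarize agreement
    per parameter; differences are oriented as (table_a − table_b)."""
    keys = list(keys)
    for name, tbl in (("first", table_a), ("second", table_b)):
        missing = [k for k in keys if k not in tbl.columns]
        if missing:
            raise AgreementError(f"{name} table lacks key column(s): {missing}")
    merged = table_a.merge(table_b, on=keys, suffixes=("_a", "_b"))
    if merged.empty:
        raise AgreementError("empty join: the tables share no keys")

    results: dict[str, ComparisonResult] = {}
    for param in parameters:
        ca, cb = f"{param}_a", f"{param}_b"
        if ca not in merged.columns or cb not in merged.columns:
            continue
        sub = merged[[ca, cb]].dropna()
        dropped = len(merged) - len(sub)
        if len(sub) < 2:
            continue
        series = PairedSeries(
            x=sub[ca].to_numpy(), y=sub[cb].to_numpy(),
            parameter=param, n_dropped=dropped,
        )
        results[param] = _compare_series(series, margin=margin)
    if not results:
        raise AgreementError("no parameter column was present in both tables")
    return results


def comparison_table(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Results as a report table, one parameter per row, fixed column order."""
    rows = [results[p].as_row() for p in AGREEMENT_PARAMETERS if p in results]
    rows += [r.as_row() for p, r in results.items() if p not in AGREEMENT_PARAMETERS]
    return pd.DataFrame(rows)


def bland_altman_plot(series: PairedSeries, path, title: str | None = None):
    """Write a Bland-Altman plot (bias line + LOA lines) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(series)
    lo, hi = limits_of_agreement(ba["bias"], ba["sd_diff"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(series.means, series.differences, s=12, alpha=0.7)
    ax.axhline(ba["bias"], color="black", ls="--", label=f"bias {ba['bias']:.2f}")
    for y, lab in ((lo, f"LOA {lo:.2f}"), (hi, f"LOA {hi:.2f}")):
        ax.axhline(y, color="tab:blue", ls="--", label=lab)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (first − second)")
    ax.set_title(title or series.parameter)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
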