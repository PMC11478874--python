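"""Performance comparison between conditions: paired t-test with a
Shapiro-Wilk normality check, and percent-change summaries.

Performance variables (sprint time, crossover time, puck velocity) are
averaged per participant and condition upstream; here the paired vectors are
compared with a two-sided paired Student's t-test (alpha = 0.05 by
convention), preceded by a Shapiro-Wilk test on the paired differences.  If
normality is rejected the t-test still runs, but the report flags the
violation.  Percent change uses the Equipment condition as the baseline
(denominator), since equipment is the reference state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestReport:
    t: float
    p: float
    df: int
    shapiro_W: float
    shapiro_p: float
    mean_a: float
    mean_b: float
    normality_ok: bool
    degenerate: bool = False  # all paired differences zero


def paired_t(a, b, alpha: float = 0.05) -> TestReport:
    """Two-sided paired Student's t-test on ``a - b`` with normality check.

    By contract, identical vectors (zero difference everywhere) are reported
    as t = 0, p = 1 rather than the indeterminate 0/0 statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D vectors of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.all(d == 0.0):
        return TestReport(
            t=0.0, p=1.0, df=n - 1, shapiro_W=np.nan, shapiro_p=np.nan,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            normality_ok=True, degenerate=True,
        )
    if np.std(d, ddof=1) == 0.0:
        raise ValueError("paired differences have zero variance; t undefined")
    sw = stats.shapiro(d)
    tt = stats.ttest_rel(a, b)
    return TestReport(
        t=float(tt.statistic),
        p=float(tt.pvalue),
        df=n - 1,
        shapiro_W=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        normality_ok=bool(sw.pvalue >= alpha),
    )


@dataclass
class PercentChangeSummary:
    mean_percent_change: float
    n_increased: int   # b < a (value decreased without equipment)
    n_decreased: int   # b > a
    n_unchanged: int
    per_participant: np.ndarray


def percent_change_summary(a, b) -> PercentChangeSummary:
    """Per-participant percent change 100*(a_i - b_i)/a_i, with ``a`` the
    baseline (Equipment) condition, plus direction counts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D vectors of equal length")
    if np.any(a <= 0.0):
        raise ValueError("baseline values must be positive for percent change")
    changes = 100.0 * (a - b) / a
    return PercentChangeSummary(
        mean_percent_change=float(changes.mean()),
        n_increased=int(np.sum(b < a)),
        n_decreased=int(np.sum(b > a)),
        n_unchanged=int(np.sum(b == a)),
        per_participant=changes,
    )


def performance_report(table, drill: str, value_col: str = "value") -> dict:
    """Paired analysis of a per-participant performance table.

    ``table`` is a DataFrame with columns participant, condition, drill and a
    value column; values are averaged per participant and condition before
    pairing (Equipment first).
    """
    sub = table[table["drill"] == drill]
    means = sub.groupby(["participant", "condition"])[value_col].mean().unstack()
    if not {"Equipment", "NoEquipment"} <= set(means.columns):
        raise ValueError("both conditions required for a paired analysis")
    means = means.dropna()
    a = means["Equipment"].to_numpy()
    b = means["NoEquipment"].to_numpy()
    rep = paired_t(a, b)
    pct = percent_change_summary(a, b)
    return {
        "drill": drill,
        "n": len(a),
        "t": rep.t,
        "p": rep.p,
        "df": rep.df,
        "shapiro_W": rep.shapiro_W,
        "shapiro_p": rep.shapiro_p,
        "normality_ok": rep.normality_ok,
        "mean_equipment": rep.mean_a,
        "mean_no_equipment": rep.mean_b,
        "mean_percent_change": pct.mean_percent_change,
        "n_increased": pct.n_increased,
        "n_decreased": pct.n_decreased,
        "n_unchanged": pct.n_unchanged,
    }
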