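"""Median-split survival comparison: Kaplan-Meier, log-rank, hazard ratio.

A cohort table (patient_id, expression, time, event) is dichotomized at the
sample median of the marker (strictly above the median = "high"), the two
groups get product-limit survival curves, and they are compared by the
Mantel-Haenszel log-rank test.  The hazard ratio of high over low expression
is the ratio of observed/expected event counts, with a 95% confidence
interval on the log scale.

Conventions: ties at the median go to the low group; censored observations
tied with an event time are still at risk at that time (event counted
first); HR < 1 means high expression carries a survival advantage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientRecord",
    "KMCurve",
    "LogRankResult",
    "HazardRatioEstimate",
    "median_split",
    "km_curve",
    "logrank_test",
    "hazard_ratio",
    "run_survival_pipeline",
]


@dataclass(frozen=True)
class PatientRecord:
    """Row schema of a cohort table."""

    patient_id: str
    expression: float
    time: float
    event: bool


@dataclass
class KMCurve:
    """Product-limit estimate at each distinct event time."""

    event_times: np.ndarray   # sorted distinct times with >= 1 event
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # number entering each event time
    n_events: np.ndarray      # events at each event time
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    degenerate: bool = False


@dataclass
class HazardRatioEstimate:
    hr: float
    ci_low: float
    ci_high: float
    method: str = "mantel-haenszel-oe"
    degenerate: bool = False


def _check_cohort(records: pd.DataFrame, need_expression: bool = True) -> None:
    req = {"time", "event"} | ({"expression"} if need_expression else set())
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s) {sorted(missing)}")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

def median_split(records: pd.DataFrame, *, statistic: str = "median"
                 ) -> tuple[pd.Series, float]:
    """Label each patient 'high' (strictly above the cutoff) or 'low'.

    The cutoff is the linear-interpolation sample median by default;
    ``statistic="mean"`` splits at the mean instead.  Returns the label
    series and the cutoff used.
    """
    _check_cohort(records)
    if len(records) < 4:
        raise ValueError("median split needs at least 4 records")
    expr = records["expression"].to_numpy(dtype=float)
    if statistic == "median":
        cutoff = float(np.median(expr))
    elif statistic == "mean":
        cutoff = float(np.mean(expr))
    else:
        raise ValueError(f"unknown split statistic {statistic!r}")
    labels = pd.Series(np.where(expr > cutoff, "high", "low"),
                       index=records.index, name="group")
    if (labels == "high").all() or (labels == "low").all():
        raise ValueError("no split possible: expressions do not straddle the cutoff")
    return labels, cutoff


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(records: pd.DataFrame) -> KMCurve:
    """Product-limit survival estimate for one group.

    At each distinct time with at least one event, S multiplies by
    (1 - d/n) where n counts everyone with follow-up >= that time, so
    censored observations tied with an event remain at risk there.
    """
    _check_cohort(records, need_expression=False)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy().astype(bool)

    ev_times = np.unique(time[event])
    at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=int)
    n_events = np.array([(event & (time == t)).sum() for t in ev_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / at_risk) if len(ev_times) else np.array([])
    return KMCurve(event_times=ev_times, survival=np.asarray(surv, dtype=float),
                   at_risk=at_risk, n_events=n_events, n_total=len(records))


# ---------------------------------------------------------------------------
# Log-rank and hazard ratio
# ---------------------------------------------------------------------------

def _logrank_tables(low: pd.DataFrame, high: pd.DataFrame):
    """Per-event-time risk-set tables: (O-E sum for high, variance, O, E)."""
    t_low = low["time"].to_numpy(dtype=float)
    e_low = low["event"].to_numpy().astype(bool)
    t_high = high["time"].to_numpy(dtype=float)
    e_high = high["event"].to_numpy().astype(bool)

    all_event_times = np.unique(np.concatenate([t_low[e_low], t_high[e_high]]))
    o_high = float(e_high.sum())
    o_low = float(e_low.sum())
    e_high_sum = 0.0
    var_sum = 0.0
    for t in all_event_times:
        n1 = float((t_high >= t).sum())
        n0 = float((t_low >= t).sum())
        n = n1 + n0
        d1 = float((e_high & (t_high == t)).sum())
        d0 = float((e_low & (t_low == t)).sum())
        d = d1 + d0
        if n == 0:
            continue
        e_high_sum += d * n1 / n
        if n > 1:
            var_sum += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    e_low_sum = (o_low + o_high) - e_high_sum
    return o_low, o_high, e_low_sum, e_high_sum, var_sum


def logrank_test(low: pd.DataFrame, high: pd.DataFrame) -> LogRankResult:
    """Mantel-Haenszel log-rank test between two groups.

    Sums observed minus hypergeometric-expected events in the high group
    over every distinct event time; chi-square = (sum O-E)^2 / sum variance
    with 1 df.  Zero total variance is flagged degenerate (p = 1).
    """
    for name, df in (("low", low), ("high", high)):
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
        _check_cohort(df, need_expression=False)
    o_low, o_high, e_low, e_high, var = _logrank_tables(low, high)
    if o_low + o_high == 0:
        raise ValueError("log-rank test needs at least one event")
    observed = {"low": o_low, "high": o_high}
    expected = {"low": e_low, "high": e_high}
    if var <= 0:
        return LogRankResult(0.0, 1, 1.0, observed, expected, var, degenerate=True)
    chi2 = (o_high - e_high) ** 2 / var
    p = float(stats.chi2.sf(chi2, 1))
    return LogRankResult(float(chi2), 1, p, observed, expected, float(var))


def hazard_ratio(low: pd.DataFrame, high: pd.DataFrame, *,
                 ci: float = 0.95) -> HazardRatioEstimate:
    """Hazard ratio of high vs low expression from observed/expected counts.

    HR = (O_high / E_high) / (O_low / E_low); the confidence interval uses
    the standard log-scale approximation se(log HR) = sqrt(1/E_high +
    1/E_low).  Zero events in either group yields 0 or inf with a
    degeneracy flag.
    """
    if not 0 < ci < 1:
        raise ValueError("confidence level must be in (0, 1)")
    o_low, o_high, e_low, e_high, _var = _logrank_tables(low, high)
    if o_low == 0 or o_high == 0:
        hr = 0.0 if o_high == 0 else math.inf
        return HazardRatioEstimate(hr, hr, hr, degenerate=True)
    hr = (o_high / e_high) / (o_low / e_low)
    se = math.sqrt(1.0 / e_high + 1.0 / e_low)
    z = float(stats.norm.ppf(0.5 + ci / 2))
    return HazardRatioEstimate(
        hr=float(hr),
        ci_low=float(hr * math.exp(-z * se)),
        ci_high=float(hr * math.exp(z * se)),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_survival_pipeline(records: pd.DataFrame, *, split: str = "median",
                          ci: float = 0.95) -> dict:
    """Median split -> per-group KM curves -> log-rank -> hazard ratio.

    Returns a JSON-serializable summary plus the two curves under
    ``"curves"`` (not serialized by the CLI summary writer).
    """
    labels, cutoff = median_split(records, statistic=split)
    low = records[labels == "low"]
    high = records[labels == "high"]
    curve_low = km_curve(low)
    curve_high = km_curve(high)
    lr = logrank_test(low, high)
    hr = hazard_ratio(low, high, ci=ci)
    return {
        "split_statistic": split,
        "cutoff": cutoff,
        "n_low": int(len(low)),
        "n_high": int(len(high)),
        "events_low": int(lr.observed["low"]),
        "events_high": int(lr.observed["high"]),
        "chi_square": lr.chi_square,
        "logrank_p": lr.p_value,
        "hazard_ratio": hr.hr,
        "hr_ci_low": hr.ci_low,
        "hr_ci_high": hr.ci_high,
        "ci_level": ci,
        "degenerate": lr.degenerate or hr.degenerate,
        "curves": {"low": curve_low, "high": curve_high},
    }
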