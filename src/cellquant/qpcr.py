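"""Relative qPCR quantification and mRNA half-life estimation.

Relative expression uses the comparative-Ct (2^-ddCt) method with a constant
reference gene (actin by default) and a calibrator sample.  Half-lives come
from actinomycin-D chase courses: after transcription is blocked, remaining
mRNA decays exponentially, so ordinary least squares of log expression on
time gives the decay rate k and half-life ln2 / k.

Replicates aggregate by arithmetic mean on the Ct scale, i.e. geometric mean
on the linear expression scale — Ct is the measured quantity.  Amplification
efficiency is fixed at 2 (perfect doubling per cycle) unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DecayCourse",
    "HalfLifeFit",
    "delta_delta_ct",
    "build_decay_course",
    "fit_half_life",
    "compare_half_lives",
]


@dataclass
class DecayCourse:
    """Normalized decay time course: expression relative to t=0 per timepoint."""

    gene: str
    times: np.ndarray        # hours post actinomycin D, strictly increasing, t[0]=0
    values: np.ndarray       # relative expression, values[0]=1 by construction

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if self.times[0] != 0:
            raise ValueError("decay course must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("expressions must be positive")


@dataclass
class HalfLifeFit:
    decay_rate: float        # k, per hour
    half_life: float         # ln2 / k hours; inf when no measurable decay
    stderr_k: float
    r_squared: float
    n_points: int
    no_decay: bool = False   # fitted k <= 0


# ---------------------------------------------------------------------------
# Relative quantification
# ---------------------------------------------------------------------------

def delta_delta_ct(records: pd.DataFrame, *, target_gene: str,
                   reference_gene: str, calibrator: str,
                   efficiency: float = 2.0) -> pd.DataFrame:
    """Comparative-Ct relative expression per sample.

    dCt = mean target Ct - mean reference Ct within each sample;
    value = efficiency^-(dCt_sample - dCt_calibrator).  The calibrator sample
    gets value 1 exactly.  Returns a table (sample, gene, value) with
    ``time_h`` carried through when present.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    req = {"sample", "gene", "ct"}
    if not req <= set(records.columns):
        raise ValueError(f"Ct table needs columns {sorted(req)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = records.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    for gene in (target_gene, reference_gene):
        if gene not in mean_ct.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_ref = mean_ct[mean_ct[reference_gene].isna()].index.tolist()
    if missing_ref:
        raise ValueError(f"missing reference-gene Ct for sample(s) {missing_ref}")
    missing_tgt = mean_ct[mean_ct[target_gene].isna()].index.tolist()
    if missing_tgt:
        raise ValueError(f"missing target-gene Ct for sample(s) {missing_tgt}")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} absent")

    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    ddct = dct - dct.loc[calibrator]
    value = np.power(float(efficiency), -ddct)

    out = pd.DataFrame({"sample": value.index, "gene": target_gene,
                        "value": value.to_numpy()})
    if "time_h" in records.columns:
        times = records.groupby("sample")["time_h"].first()
        out["time_h"] = times.reindex(out["sample"]).to_numpy()
        out = out.sort_values("time_h", kind="stable").reset_index(drop=True)
    return out


def build_decay_course(rel: pd.DataFrame, *, gene: str | None = None) -> DecayCourse:
    """Normalize relative expressions to the t=0 value.

    ``rel`` needs columns (value, time_h); several rows per timepoint are
    aggregated by geometric mean before normalization.
    """
    req = {"value", "time_h"}
    if not req <= set(rel.columns):
        raise ValueError(f"relative-expression table needs columns {sorted(req)}")
    if (rel["value"] <= 0).any():
        raise ValueError("relative expressions must be positive")
    gm = rel.groupby("time_h")["value"].apply(
        lambda v: float(np.exp(np.mean(np.log(v)))))
    gm = gm.sort_index()
    if 0.0 not in gm.index:
        raise ValueError("decay course requires a t=0 timepoint")
    if gene is None:
        gene = str(rel["gene"].iloc[0]) if "gene" in rel.columns else ""
    return DecayCourse(gene=gene, times=gm.index.to_numpy(dtype=float),
                       values=(gm / gm.loc[0.0]).to_numpy())


# ---------------------------------------------------------------------------
# Half-life fitting
# ---------------------------------------------------------------------------

def fit_half_life(course: DecayCourse) -> HalfLifeFit:
    """OLS of log expression on time; k = -slope, half-life = ln2 / k.

    A non-positive fitted k is flagged ``no_decay`` with infinite half-life.
    """
    if len(course.times) < 3:
        raise ValueError("half-life fit needs at least 3 timepoints")
    res = stats.linregress(course.times, np.log(course.values))
    k = -float(res.slope)
    r2 = float(res.rvalue ** 2) if not math.isnan(res.rvalue) else 0.0
    if k <= 0:
        return HalfLifeFit(decay_rate=k, half_life=math.inf,
                           stderr_k=float(res.stderr), r_squared=r2,
                           n_points=len(course.times), no_decay=True)
    return HalfLifeFit(decay_rate=k, half_life=math.log(2) / k,
                       stderr_k=float(res.stderr), r_squared=r2,
                       n_points=len(course.times))


def fit_half_life_nls(course: DecayCourse) -> HalfLifeFit:
    """Nonlinear least-squares exponential fit, A * exp(-k t), as a cross-check."""
    from scipy.optimize import curve_fit

    def model(t, a, k):
        return a * np.exp(-k * t)

    p0 = (1.0, max(1e-6, fit_half_life(course).decay_rate))
    popt, pcov = curve_fit(model, course.times, course.values, p0=p0, maxfev=10000)
    k = float(popt[1])
    resid = course.values - model(course.times, *popt)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((course.values - course.values.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    if k <= 0:
        return HalfLifeFit(k, math.inf, stderr, r2, len(course.times), no_decay=True)
    return HalfLifeFit(k, math.log(2) / k, stderr, r2, len(course.times))


def compare_half_lives(courses: dict[str, DecayCourse]
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-condition fits plus a pooled test of equal decay slopes.

    The slope-equality test compares a pooled log-linear model with a common
    slope against one with condition-specific slopes (interaction F test).
    """
    if len(courses) < 2:
        raise ValueError("need at least 2 conditions to compare")
    fits = {cond: fit_half_life(c) for cond, c in courses.items()}
    table = pd.DataFrame([{
        "condition": cond,
        "decay_rate": f.decay_rate,
        "half_life": f.half_life,
        "stderr_k": f.stderr_k,
        "r_squared": f.r_squared,
        "no_decay": f.no_decay,
    } for cond, f in fits.items()])

    conds = list(courses)
    rows = []
    for ci, cond in enumerate(conds):
        c = courses[cond]
        for t, v in zip(c.times, c.values):
            rows.append((ci, t, math.log(v)))
    df = pd.DataFrame(rows, columns=["cond", "time", "logv"])

    dummies = pd.get_dummies(df["cond"], drop_first=True, dtype=float)
    x_common = pd.concat([dummies, df["time"]], axis=1)
    x_full = x_common.copy()
    for col in dummies.columns:
        x_full[f"t_x_{col}"] = dummies[col] * df["time"]
    fit_r = sm.OLS(df["logv"], sm.add_constant(x_common.to_numpy())).fit()
    fit_f = sm.OLS(df["logv"], sm.add_constant(x_full.to_numpy())).fit()
    f_stat, p_value, df_diff = fit_f.compare_f_test(fit_r)
    slope_test = {"f_stat": float(f_stat), "p_value": float(p_value),
                  "df_num": float(df_diff), "df_den": float(fit_f.df_resid)}
    return table, slope_test
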