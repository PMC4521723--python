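"""Longitudinal analysis: variability, change onset, IOP dose, sequencing.

The longitudinal design is a unilateral experimental-glaucoma study: one
eye of each animal is lasered (EG), the fellow eye is the control. For
each structural parameter (mean ALCSD, mean MRW, mean RoC, RNFLT, and the
pore-geometry composite):

1. control-eye repeatability across visits gives a 95% interval
   (mean ± 1.96·SD of the repeated measurements, a tolerance interval for
   a single new observation),
2. the first change in the EG eye is the earliest visit whose value falls
   outside that interval with *no subsequent visit returning inside*,
3. onset days are dense-ranked within each eye and averaged across eyes,
   and event-based Kaplan–Meier curves with pairwise log-rank tests
   compare the onset timing across parameters.

Cumulative IOP difference (mmHg·days) integrates each eye's IOP over time
from the first laser day and subtracts control from EG.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.integrate import cumulative_trapezoid

from .spatial import rank_sum_test

__all__ = [
    "StudySeries",
    "RepeatabilityStats",
    "OnsetRecord",
    "SurvivalResult",
    "repeatability_stats",
    "confidence_interval",
    "pooled_interval",
    "detect_first_change",
    "pore_change_onset",
    "cumulative_iop_difference",
    "onset_positions",
    "km_logrank",
    "inter_eye_summary",
    "round_half_up",
]

PARAMETERS = ("alcsd", "mrw", "pores", "roc", "rnflt")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the rounding used in printed tables).

    A pre-round six decimals below the target absorbs binary float error,
    so a value that is exactly x.x5 in decimal arithmetic but stored as
    x.x4999…9 still rounds up.
    """
    if not math.isfinite(x):
        return x
    x = float(np.round(x, decimals + 6))
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class StudySeries:
    """Per-eye longitudinal parameter values and IOP vs days post-laser."""

    eye_id: str
    role: str  # "control" | "EG"
    days: np.ndarray  # sorted, day 0 = first laser
    values: dict[str, np.ndarray]  # parameter name -> per-visit values
    iop: np.ndarray | None = None  # mmHg per visit

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("visit days must be strictly increasing")
        if self.days[0] > 0:
            raise ValueError("need at least one baseline (pre-laser) visit")
        if self.role not in ("control", "EG"):
            raise ValueError("role must be 'control' or 'EG'")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if len(v) != len(self.days):
                raise ValueError(f"parameter {k!r}: length mismatch with days")
        if self.iop is not None:
            self.iop = np.asarray(self.iop, dtype=float)


@dataclass
class RepeatabilityStats:
    mean: float
    sd: float
    cor: float  # coefficient of repeatability, 1.96·SD·√2
    cov: float  # coefficient of variation, 100·SD/mean (%)
    ci_low: float
    ci_high: float
    n: int


def repeatability_stats(values, ci_style: str = "sd") -> RepeatabilityStats:
    """Mean, SD (n−1), CoR = 1.96·SD·√2, CoV = 100·SD/mean and the 95%
    interval for a control-eye series.

    ``ci_style='sd'`` (default) builds the interval as mean ± 1.96·SD — a
    tolerance interval for a single new measurement, which is what the
    onset rule needs (individual EG visits are compared against it);
    ``'se'`` gives the narrower mean ± 1.96·SD/√n.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("repeatability needs at least 3 time-points")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0:
        raise ZeroDivisionError("mean is zero: CoV undefined")
    half = 1.96 * sd if ci_style == "sd" else 1.96 * sd / math.sqrt(len(x))
    return RepeatabilityStats(
        mean=mean,
        sd=sd,
        cor=1.96 * sd * math.sqrt(2.0),
        cov=100.0 * sd / abs(mean),
        ci_low=mean - half,
        ci_high=mean + half,
        n=len(x),
    )


def confidence_interval(values, ci_style: str = "sd") -> tuple[float, float]:
    st = repeatability_stats(values, ci_style=ci_style)
    return st.ci_low, st.ci_high


def pooled_interval(series_list: list[np.ndarray], ci_style: str = "sd") -> tuple[float, float]:
    """95% interval from the pooled distribution of several control-eye
    series (the fallback when an animal has no usable fellow control)."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in series_list])
    return confidence_interval(pooled, ci_style=ci_style)


# --------------------------------------------------------------------------
# first-change detection
# --------------------------------------------------------------------------

@dataclass
class OnsetRecord:
    eye_id: str
    parameter: str
    onset_day: float  # day of first sustained excursion; last day if censored
    censored: bool
    direction: str = ""  # "increase" | "decrease" | "" when censored
    position: int | None = None  # dense rank within the eye, filled later


def detect_first_change(days, values, interval: tuple[float, float],
                        eye_id: str = "", parameter: str = "") -> OnsetRecord:
    """First sustained excursion of an EG series outside a control interval.

    The onset is the earliest day whose value lies outside
    ``interval=(low, high)`` *and* for which every later value is also
    outside (the no-return clause: a transient excursion that returns
    inside the interval does not count). If no such day exists the record
    is censored at the last observed day. The direction notes the side on
    which the interval was exited at onset.
    """
    low, high = interval
    if not (math.isfinite(low) and math.isfinite(high)) or low > high:
        raise ValueError("interval must be finite with low <= high")
    days = np.asarray(days, dtype=float)
    vals = np.asarray(values, dtype=float)
    if len(days) == 0 or len(days) != len(vals):
        raise ValueError("need matching, non-empty days and values")
    # relative tolerance so a degenerate (zero-width) interval from a
    # constant series does not flag values equal to the bound up to 1 ulp
    tol = 1e-9 * max(abs(low), abs(high), 1.0)
    outside = (vals < low - tol) | (vals > high + tol)
    # sustained from index i onward means every visit from i is outside
    sustained = np.logical_and.accumulate(outside[::-1])[::-1]
    idx = np.flatnonzero(sustained)
    if len(idx) == 0:
        return OnsetRecord(eye_id, parameter, float(days[-1]), censored=True)
    i = int(idx[0])
    direction = "increase" if vals[i] > high else "decrease"
    return OnsetRecord(eye_id, parameter, float(days[i]), censored=False, direction=direction)


def pore_change_onset(
    pore_values: dict[float, dict[str, dict[str, np.ndarray]]],
    eye_id: str = "",
    alpha: float = 0.05,
    min_baseline: int = 2,
) -> OnsetRecord:
    """Eye-level onset of change in ALCS pore geometry.

    ``pore_values`` maps visit day -> partition (region or sector name) ->
    parameter ("area" | "elongation" | "nnd") -> per-pore values at that
    visit. The procedure mirrors the ONH-parameter rule but must build its
    own reference interval, since pores have no stable fellow-eye scale:

    1. *Baseline growth*: starting from the pre-laser visits (day <= 0),
       follow-up visits are added to the baseline set for as long as every
       pore parameter is rank-sum non-significant against the pooled
       baseline pores (p > alpha), pooling each parameter across the
       partitions shared with baseline. (Testing every parameter ×
       partition separately would stop the growth at the first follow-up
       almost surely — 15 tests at alpha = .05 — and leave the intervals
       with useless degrees of freedom.) Partitions absent at a visit or
       at baseline are skipped.
    2. *Intervals*: per parameter × partition, a 95% interval
       (mean ± 1.96·SD) of the baseline per-visit means.
    3. *Onset*: the earliest day at which any parameter × partition mean
       falls outside its interval with no later return; the eye-level
       onset is the minimum over partitions. Censored at the last visit
       when nothing changes.
    """
    days = sorted(pore_values)
    baseline_days = [d for d in days if d <= 0]
    if len(baseline_days) < min_baseline:
        # allow early follow-ups to seed the baseline when <2 pre-laser visits
        baseline_days = days[:min_baseline]
    if len(baseline_days) < min_baseline:
        raise ValueError(f"need at least {min_baseline} baseline-eligible time-points")

    def partitions_at(day):
        return set(pore_values[day])

    def params_at(day, part):
        return set(pore_values[day][part])

    # 1. grow the baseline set forward (global per-parameter tests over
    #    the partitions shared with baseline)
    baseline = list(baseline_days)
    for day in days:
        if day in baseline:
            continue
        stable = True
        for param in ("area", "elongation", "nnd"):
            visit_vals, base_vals = [], []
            for part in partitions_at(day):
                base_days_with = [d for d in baseline if part in pore_values[d]
                                  and param in pore_values[d][part]]
                if not base_days_with or param not in pore_values[day][part]:
                    continue  # partition not shared with baseline: skip
                visit_vals.append(pore_values[day][part][param])
                base_vals.extend(pore_values[d][part][param] for d in base_days_with)
            if not visit_vals or not base_vals:
                continue
            visit_pool = np.concatenate(visit_vals)
            base_pool = np.concatenate(base_vals)
            if len(visit_pool) and len(base_pool) \
                    and rank_sum_test(visit_pool, base_pool).p_value <= alpha:
                stable = False
                break
        if not stable:
            break
        baseline.append(day)

    # 2. intervals from baseline per-visit means
    intervals: dict[tuple[str, str], tuple[float, float]] = {}
    for part in set().union(*(partitions_at(d) for d in baseline)):
        for param in ("area", "elongation", "nnd"):
            means = [
                float(np.mean(pore_values[d][part][param]))
                for d in baseline
                if part in pore_values[d] and param in pore_values[d][part]
                and len(pore_values[d][part][param])
            ]
            if len(means) >= 2:
                m, sd = float(np.mean(means)), float(np.std(means, ddof=1))
                intervals[(part, param)] = (m - 1.96 * sd, m + 1.96 * sd)

    # 3. earliest sustained excursion over any parameter × partition
    onset_day = None
    direction = ""
    for (part, param), interval in intervals.items():
        series_days = [d for d in days if part in pore_values[d] and param in pore_values[d][part]
                       and len(pore_values[d][part][param])]
        series_vals = [float(np.mean(pore_values[d][part][param])) for d in series_days]
        rec = detect_first_change(series_days, series_vals, interval)
        if not rec.censored and (onset_day is None or rec.onset_day < onset_day):
            onset_day = rec.onset_day
            direction = rec.direction
    if onset_day is None:
        return OnsetRecord(eye_id, "pores", float(days[-1]), censored=True)
    return OnsetRecord(eye_id, "pores", float(onset_day), censored=False, direction=direction)


# --------------------------------------------------------------------------
# IOP dose
# --------------------------------------------------------------------------

def cumulative_iop_difference(
    eg_days, eg_iop, ctl_days, ctl_iop
) -> pd.DataFrame:
    """Cumulative IOP difference (EG − control) in mmHg·days.

    Each eye's IOP is integrated (trapezoid rule) from day 0 up to every
    visit; series on different visit grids are first linearly interpolated
    to the union of days. Returns a frame with columns ``day``,
    ``cum_eg``, ``cum_ctl``, ``cum_diff``.
    """
    eg_days = np.asarray(eg_days, dtype=float)
    ctl_days = np.asarray(ctl_days, dtype=float)
    if np.any(eg_days < 0) or np.any(ctl_days < 0):
        raise ValueError("IOP integration starts at day 0 (post-laser); negative days given")
    days = np.union1d(eg_days, ctl_days)
    eg = np.interp(days, eg_days, np.asarray(eg_iop, dtype=float))
    ctl = np.interp(days, ctl_days, np.asarray(ctl_iop, dtype=float))
    cum_eg = cumulative_trapezoid(eg, days, initial=0.0)
    cum_ctl = cumulative_trapezoid(ctl, days, initial=0.0)
    return pd.DataFrame({"day": days, "cum_eg": cum_eg, "cum_ctl": cum_ctl,
                         "cum_diff": cum_eg - cum_ctl})


# --------------------------------------------------------------------------
# onset ranking and survival
# --------------------------------------------------------------------------

def onset_positions(onsets: list[OnsetRecord]) -> pd.DataFrame:
    """Dense-rank onset days within each eye and average positions across eyes.

    Within an eye, distinct onset days are ranked 1, 2, ... with ties
    sharing a position (dense ranking); censored parameters receive no
    position and are excluded from that parameter's mean. Returns one row
    per parameter with ``mean_position`` and ``n_eyes``.
    """
    by_eye: dict[str, list[OnsetRecord]] = {}
    for rec in onsets:
        by_eye.setdefault(rec.eye_id, []).append(rec)
    for recs in by_eye.values():
        events = sorted({r.onset_day for r in recs if not r.censored})
        rank = {day: i + 1 for i, day in enumerate(events)}
        for r in recs:
            r.position = rank[r.onset_day] if not r.censored else None

    params = sorted({r.parameter for r in onsets},
                    key=lambda p: PARAMETERS.index(p) if p in PARAMETERS else 99)
    rows = []
    for p in params:
        pos = [r.position for r in onsets if r.parameter == p and r.position is not None]
        rows.append({
            "parameter": p,
            "mean_position": float(np.mean(pos)) if pos else math.nan,
            "n_eyes": len(pos),
        })
    return pd.DataFrame(rows)


@dataclass
class SurvivalResult:
    """KM step functions per parameter plus pairwise log-rank tests."""

    curves: dict[str, pd.DataFrame]  # parameter -> columns day, survival, at_risk
    pairwise: pd.DataFrame  # columns param_a, param_b, chi2, p
    global_test: tuple[float, float] | None = None  # (chi2, p) across all groups
    warnings: list[str] = field(default_factory=list)


def km_logrank(onsets: list[OnsetRecord], global_test: bool = False) -> SurvivalResult:
    """Event-based Kaplan–Meier curves and log-rank comparisons.

    Each parameter is one group; an eye contributes its onset day as the
    event time, censored at the last visit when no sustained change was
    found. Pairwise two-group log-rank tests (1 df) are reported for all
    parameter pairs; a global multi-group test is optional.
    """
    params = sorted({r.parameter for r in onsets},
                    key=lambda p: PARAMETERS.index(p) if p in PARAMETERS else 99)
    if len(params) < 2:
        raise ValueError("survival sequencing needs at least 2 parameters")
    warnings = []
    curves: dict[str, pd.DataFrame] = {}
    grouped: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p in params:
        recs = [r for r in onsets if r.parameter == p]
        t = np.array([r.onset_day for r in recs], dtype=float)
        e = np.array([not r.censored for r in recs], dtype=bool)
        grouped[p] = (t, e)
        if not e.any():
            warnings.append(f"parameter {p!r} has zero events; its comparisons are weak")
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[p] = pd.DataFrame({
            "day": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.to_numpy(dtype=float),
        })

    rows = []
    for a, b in itertools.combinations(params, 2):
        ta, ea = grouped[a]
        tb, eb = grouped[b]
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        rows.append({"param_a": a, "param_b": b,
                     "chi2": float(res.test_statistic), "p": float(res.p_value)})
    pairwise = pd.DataFrame(rows)

    gt = None
    if global_test:
        t_all = np.concatenate([grouped[p][0] for p in params])
        e_all = np.concatenate([grouped[p][1] for p in params])
        g_all = np.concatenate([np.full(len(grouped[p][0]), p) for p in params])
        res = multivariate_logrank_test(t_all, g_all, e_all)
        gt = (float(res.test_statistic), float(res.p_value))
    return SurvivalResult(curves=curves, pairwise=pairwise, global_test=gt, warnings=warnings)


# --------------------------------------------------------------------------
# fellow-eye agreement
# --------------------------------------------------------------------------

def inter_eye_summary(pairs: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Mean absolute inter-eye difference (± SD) and the same as a percent
    of the per-animal mean.

    ``pairs`` has one row per animal with columns ``<param>_od`` and
    ``<param>_os``; animals missing either eye are skipped (logged in the
    returned ``n``). Returns one row per parameter with ``mean_abs_diff``,
    ``sd_abs_diff``, ``mean_pct_diff``, ``sd_pct_diff``, ``n``.
    """
    if value_cols is None:
        value_cols = sorted({c[:-3] for c in pairs.columns if c.endswith("_od")})
    rows = []
    for param in value_cols:
        od = pairs[f"{param}_od"].to_numpy(dtype=float)
        os_ = pairs[f"{param}_os"].to_numpy(dtype=float)
        ok = np.isfinite(od) & np.isfinite(os_)
        if ok.sum() < 2:
            raise ValueError(f"{param}: need at least 2 complete fellow-eye pairs")
        diff = np.abs(od[ok] - os_[ok])
        pct = 100.0 * diff / ((od[ok] + os_[ok]) / 2.0)
        rows.append({
            "parameter": param,
            "mean_abs_diff": float(diff.mean()),
            "sd_abs_diff": float(diff.std(ddof=1)),
            "mean_pct_diff": float(pct.mean()),
            "sd_pct_diff": float(pct.std(ddof=1)),
            "n": int(ok.sum()),
        })
    return pd.DataFrame(rows)
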