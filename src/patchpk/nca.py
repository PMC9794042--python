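"""Noncompartmental analysis of concentration-time profiles.

Implements the weekly-window NCA used for the extended-regimen summaries:
Cmax / Tmax within each one-week wear window, AUC(0-168) by the linear-up /
log-down trapezoidal rule, average (steady-state) concentrations Css as
AUC divided by window length, per-subject accumulation ratios against a
reference week, and the arithmetic/geometric summary statistics reported in
the weekly tables.

Concentrations are pg/mL; AUCs are reported in h*ng/mL (pg*h/mL / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .structural import WEEK_H, ConcProfile

PG_PER_NG = 1000.0

#: NCA parameter columns in the weekly-table order
PARAM_COLUMNS = [
    "cmax", "tmax", "auc_0_168", "css_0_168", "css_48_168", "ar_cmax", "ar_auc",
]
STAT_ROWS = ["N", "Mean", "SD", "CV%", "Geometric mean", "Geometric CV%"]


def round_sig(x, sig: int = 3):
    """Round to ``sig`` significant figures (vectorized; NaN passes through)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = (x != 0) & np.isfinite(x)
    mag = np.floor(np.log10(np.abs(np.where(nz, x, 1.0))))
    factor = 10.0 ** (sig - 1 - mag)
    out = np.where(nz, np.round(x * factor) / factor, x)
    return out if out.shape else float(out)


def _locate(times: np.ndarray, t: float) -> int:
    idx = np.flatnonzero(np.isclose(times, t, rtol=0.0, atol=1e-6))
    if idx.size == 0:
        raise InputError(f"window bound {t} h is not a grid point of the profile")
    return int(idx[0])


def auc_lin_up_log_down(times, conc, t_start: float, t_end: float) -> float:
    """AUC over [t_start, t_end] by the linear-up / log-down rule, h*ng/mL.

    Rising or flat intervals (C2 >= C1) and intervals touching zero use the
    linear trapezoid; strictly falling positive intervals use the logarithmic
    trapezoid (C1-C2)*dt/ln(C1/C2), which is exact on monoexponential decay.
    Both bounds must be grid points.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    i0, i1 = _locate(times, t_start), _locate(times, t_end)
    if i1 < i0:
        raise InputError("t_end must not precede t_start")
    t = times[i0 : i1 + 1]
    c = conc[i0 : i1 + 1]
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    down = (c1 > c2) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_area = (c1 - c2) * dt / np.log(np.where(down, c1 / np.where(c2 > 0, c2, 1.0), np.e))
    lin_area = 0.5 * (c1 + c2) * dt
    return float(np.sum(np.where(down, log_area, lin_area))) / PG_PER_NG


def cmax_tmax(profile: ConcProfile, window: tuple[float, float]) -> tuple[float, float]:
    """Maximum concentration and its earliest time, elapsed within the window."""
    t_start, t_end = window
    sub = profile.window(t_start, t_end)
    if sub.times.size == 0:
        raise InputError(f"window [{t_start}, {t_end}] contains no samples")
    i = int(np.argmax(sub.conc))  # argmax returns the earliest tie
    return float(sub.conc[i]), float(sub.times[i] - t_start)


def css(auc: float, t_start: float, t_end: float) -> float:
    """Average concentration over the window: AUC/(t_end - t_start), pg/mL."""
    if not t_end > t_start:
        raise InputError("window must have positive length")
    return auc * PG_PER_NG / (t_end - t_start)


def accumulation_ratio(value_week: float, value_ref: float) -> float:
    """Ratio of a per-subject NCA value to the same subject's reference week."""
    if not value_ref > 0:
        raise InputError(f"reference value must be positive (got {value_ref})")
    return value_week / value_ref


@dataclass(frozen=True)
class SummaryStats:
    """Arithmetic and geometric summary of one NCA parameter."""

    n: int
    mean: float
    sd: float
    cv_pct: float
    geo_mean: float
    geo_cv_pct: float


def summarize(values) -> SummaryStats:
    """Arithmetic mean/SD/CV% and geometric mean / geometric CV%.

    Geometric CV% is the log-normal form 100*sqrt(exp(s^2)-1) with s the
    sample SD of natural logs.  All values must be positive.
    """
    ser = pd.Series(values, dtype=float)
    if len(ser) < 2:
        raise InputError("summary statistics need n >= 2")
    bad = ser[~(ser > 0)]
    if len(bad):
        raise InputError(
            f"geometric statistics need positive values; offending entries: "
            f"{list(bad.index[:5])}"
        )
    x = ser.to_numpy()
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    logs = np.log(x)
    s = float(np.std(logs, ddof=1))
    return SummaryStats(
        n=len(x),
        mean=mean,
        sd=sd,
        cv_pct=100.0 * sd / mean,
        geo_mean=float(np.exp(np.mean(logs))),
        geo_cv_pct=100.0 * float(np.sqrt(np.expm1(s**2))),
    )


def week_window(week: int) -> tuple[float, float]:
    """The wear-week window [(w-1)*168, w*168] hours, endpoints inclusive."""
    if week < 1:
        raise InputError("week index must be >= 1")
    return (week - 1) * WEEK_H, week * WEEK_H


def nca_for_profile(profile: ConcProfile, weeks: Sequence[int], ref_week: int = 1) -> pd.DataFrame:
    """Per-week NCA parameters for one subject (tidy one-row-per-week frame)."""
    rows = {}
    for week in sorted(set(weeks) | {ref_week}):
        t0, t1 = week_window(week)
        cmax, tmax = cmax_tmax(profile, (t0, t1))
        auc = auc_lin_up_log_down(profile.times, profile.conc, t0, t1)
        auc48 = auc_lin_up_log_down(profile.times, profile.conc, t0 + 48.0, t1)
        rows[week] = {
            "subject_id": profile.subject_id,
            "week": week,
            "cmax": cmax,
            "tmax": tmax,
            "auc_0_168": auc,
            "css_0_168": css(auc, t0, t1),
            "css_48_168": css(auc48, t0 + 48.0, t1),
        }
    ref = rows[ref_week]
    for week, r in rows.items():
        if week == ref_week:
            r["ar_cmax"] = np.nan
            r["ar_auc"] = np.nan
        else:
            r["ar_cmax"] = accumulation_ratio(r["cmax"], ref["cmax"])
            r["ar_auc"] = accumulation_ratio(r["auc_0_168"], ref["auc_0_168"])
    return pd.DataFrame([rows[w] for w in sorted(set(weeks))])


def nca_by_week(
    profiles: Iterable[ConcProfile],
    weeks: Sequence[int] = (1, 3, 12),
    ref_week: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject NCA plus the weekly summary table.

    Returns ``(per_subject, summary)``.  ``summary`` has a (week, statistic)
    row index and one column per NCA parameter; cells that the weekly tables
    mark "NC" (all Tmax summaries; AR statistics in the reference week) are
    NaN, with N = 0 for the reference-week AR columns.
    """
    profiles = list(profiles)
    missing = []
    frames = []
    for p in profiles:
        try:
            frames.append(nca_for_profile(p, weeks, ref_week))
        except InputError:
            missing.append(p.subject_id)
    if missing:
        raise InputError(f"profiles missing requested week windows: {missing}")
    per_subject = pd.concat(frames, ignore_index=True)

    records = []
    for week in sorted(set(weeks)):
        sub = per_subject[per_subject["week"] == week]
        cells = {stat: {} for stat in STAT_ROWS}
        for col in PARAM_COLUMNS:
            vals = sub[col].dropna()
            if col == "tmax":
                cells["N"][col] = len(vals)
                continue  # Tmax summaries are not calculated
            if len(vals) == 0:
                cells["N"][col] = 0
                continue
            s = summarize(vals)
            cells["N"][col] = s.n
            cells["Mean"][col] = s.mean
            cells["SD"][col] = s.sd
            cells["CV%"][col] = s.cv_pct
            cells["Geometric mean"][col] = s.geo_mean
            cells["Geometric CV%"][col] = s.geo_cv_pct
        for stat in STAT_ROWS:
            records.append({"week": week, "statistic": stat, **cells[stat]})
    summary = pd.DataFrame(records).set_index(["week", "statistic"])[PARAM_COLUMNS]
    return per_subject, summary


def format_summary_table(summary: pd.DataFrame, sig: int = 3) -> pd.DataFrame:
    """Display form of the weekly summary: significant figures and "NC" cells."""
    def fmt(v):
        if isinstance(v, float) and np.isnan(v):
            return "NC"
        if isinstance(v, float):
            return f"{round_sig(v, sig):g}"
        return v

    out = summary.copy()
    for col in out.columns:
        out[col] = [
            int(v) if stat == "N" and np.isfinite(v) else fmt(v)
            for (week, stat), v in out[col].items()
        ]
    return out
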