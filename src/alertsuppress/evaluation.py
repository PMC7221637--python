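"""Pilot evaluation metrics: weekly aggregates, per-order ratios,
signal-to-noise, one-sided Welch tests, smoothed daily curves, and the
monitoring report.

Conventions:

* weeks are ISO weeks (Monday start) — alert volume has a strong weekly
  pattern (quiet Wednesdays, very quiet weekends), so arm comparisons are
  made on whole-week aggregates;
* alerts-per-order = fired alerts / orders, an inverse efficiency measure
  computed from counts accumulated over each arm ("bulk" version) as well
  as from the means of the weekly counts;
* signal-to-noise maps useful outcomes to signal and ignored alerts with
  no follow-up to noise: with orders as signal, SNR = orders /
  (alerts − orders); with interacted alerts (which include orders) as
  signal, SNR = interacted / (alerts − interacted).  Both equal
  r / (1 − r) where r is the corresponding per-alert rate;
* arm comparisons use the one-sided Welch (unequal-variance) two-sample
  t-test with Welch–Satterthwaite degrees of freedom, alternative
  "on < off" — the pooled-variance test does not reproduce reference
  summary p-values, the Welch form does;
* the daily acceptance curve is a centered rolling mean over weekdays
  only (weekend volumes are too small to be stable), truncated at the
  endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .alert_log import AlertLog, interaction_mask
from .pipeline import PilotLog

__all__ = [
    "WeeklyStats",
    "SnrResult",
    "ComparisonResult",
    "UndefinedMetricError",
    "weekly_aggregate",
    "alerts_per_order",
    "snr",
    "percent_change",
    "welch_one_sided",
    "compare_on_off",
    "smoothed_daily_rate",
    "build_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A ratio's denominator is zero (e.g. zero orders, zero noise)."""


@dataclass
class SnrResult:
    definition: Literal["orders_as_signal", "interacted_as_signal"]
    snr_on: float | None
    snr_off: float | None
    percent_increase: float | None


@dataclass
class ComparisonResult:
    metric: str
    mean_on: float
    sd_on: float
    n_on: int
    mean_off: float
    sd_off: float
    n_off: int
    t_statistic: float
    df: float
    p_value: float
    direction: str = "on < off"


def weekly_aggregate(log: AlertLog,
                     arm_of_date=None) -> pd.DataFrame:
    """Per-ISO-week counts recomputed from raw events.

    Returns one row per (ISO year, ISO week) with the appointment count
    (all events, fired or suppressed), fired alert count, interacted
    count, order count and suppressed count; plus the pilot arm when an
    ``arm_of_date`` callable is given (the week's arm is taken from its
    Monday).
    """
    ev = log.events
    if ev.empty:
        return pd.DataFrame(columns=["iso_year", "iso_week", "appointments",
                                     "alerts", "interacted", "orders",
                                     "suppressed"])
    iso = ev["service_date"].dt.isocalendar()
    grp = ev.assign(iso_year=iso["year"], iso_week=iso["week"],
                    _inter=interaction_mask(ev))
    out = (grp.groupby(["iso_year", "iso_week"], as_index=False)
           .agg(appointments=("alert_id", "size"),
                alerts=("fired", "sum"),
                interacted=("_inter", "sum"),
                orders=("order_placed", "sum"),
                suppressed=("suppressed", "sum")))
    if arm_of_date is not None:
        mondays = [pd.Timestamp.fromisocalendar(int(y), int(w), 1)
                   for y, w in zip(out["iso_year"], out["iso_week"])]
        out["arm"] = [arm_of_date(m.date()) for m in mondays]
    return out


def alerts_per_order(alert_count: float, order_count: float) -> float:
    """Fired alerts per vaccine order placed."""
    if order_count <= 0:
        raise UndefinedMetricError(
            "alerts-per-order undefined with zero orders")
    return alert_count / order_count


def snr(alert_count: float, interacted_count: float | None,
        order_count: float | None,
        definition: Literal["orders_as_signal",
                            "interacted_as_signal"]) -> float:
    """Signal-to-noise ratio of an arm's (weekly-average) alert counts.

    Signal is the chosen useful outcome; noise is the remaining, ignored
    alerts with no follow-up.  Zero signal gives SNR 0; zero noise
    (signal == alerts) is undefined.
    """
    if definition == "orders_as_signal":
        signal = order_count
    elif definition == "interacted_as_signal":
        signal = interacted_count
    else:
        raise ValueError(f"unknown definition {definition!r}")
    if signal is None:
        raise ValueError(f"{definition} requires the corresponding count")
    if signal < 0 or signal > alert_count:
        raise ValueError("signal count outside [0, alert count]")
    if signal == 0:
        return 0.0
    noise = alert_count - signal
    if noise == 0:
        raise UndefinedMetricError("zero noise: SNR undefined")
    return signal / noise


def percent_change(before: float, after: float) -> float:
    """100 · (after − before) / before."""
    if before == 0:
        raise UndefinedMetricError("percent change from zero baseline")
    return 100.0 * (after - before) / before


def welch_one_sided(mean_on: float, sd_on: float, n_on: int,
                    mean_off: float, sd_off: float, n_off: int
                    ) -> tuple[float, float, float]:
    """Welch t-test from summaries; one-sided alternative "on < off".

    Returns (t, Welch–Satterthwaite df, p).  Computable directly from
    printed (mean, SD, n) summaries.
    """
    if n_on < 2 or n_off < 2:
        raise ValueError("need n >= 2 per arm")
    v_on, v_off = sd_on ** 2 / n_on, sd_off ** 2 / n_off
    se2 = v_on + v_off
    if se2 == 0:
        return 0.0, float(n_on + n_off - 2), 0.5
    t = (mean_on - mean_off) / np.sqrt(se2)
    df = se2 ** 2 / (v_on ** 2 / (n_on - 1) + v_off ** 2 / (n_off - 1))
    p = float(stats.t.cdf(t, df))
    return float(t), float(df), p


def compare_on_off(values_on, values_off, metric: str = "") -> ComparisonResult:
    """One-sided Welch comparison of weekly metric values between arms."""
    on = np.asarray(values_on, float)
    off = np.asarray(values_off, float)
    if len(on) < 2 or len(off) < 2:
        raise ValueError("need >= 2 weeks per arm")
    t, df, p = welch_one_sided(on.mean(), on.std(ddof=1), len(on),
                               off.mean(), off.std(ddof=1), len(off))
    return ComparisonResult(metric=metric,
                            mean_on=float(on.mean()),
                            sd_on=float(on.std(ddof=1)), n_on=len(on),
                            mean_off=float(off.mean()),
                            sd_off=float(off.std(ddof=1)), n_off=len(off),
                            t_statistic=t, df=df, p_value=p)


def smoothed_daily_rate(log: AlertLog, window: int = 5) -> pd.DataFrame:
    """Centered rolling mean of the daily acceptance rate over weekdays.

    Weekends are dropped before smoothing; endpoint windows truncate.
    Returns columns (date, n_fired, n_interacted, rate, smoothed).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ev = log.events
    daily = (ev.assign(_inter=interaction_mask(ev))
             .groupby("service_date", as_index=False)
             .agg(n_fired=("fired", "sum"), n_interacted=("_inter", "sum")))
    daily = daily.loc[daily["service_date"].dt.weekday < 5].reset_index(
        drop=True)
    with np.errstate(invalid="ignore"):
        daily["rate"] = np.where(daily["n_fired"] > 0,
                                 daily["n_interacted"] / daily["n_fired"],
                                 np.nan)
    daily["smoothed"] = (daily["rate"]
                         .rolling(window, center=True, min_periods=1)
                         .mean())
    return daily.rename(columns={"service_date": "date"})


def _volume_anomalies(daily: pd.DataFrame, k: float = 3.0,
                      trailing: int = 28) -> list[str]:
    """Dates whose weekday alert volume strays k SDs from the trailing mean."""
    flags = []
    vols = daily["n_fired"].to_numpy(float)
    dates = daily["date"].dt.date.to_numpy()
    for i in range(len(daily)):
        lo = max(0, i - trailing)
        past = vols[lo:i]
        if len(past) < 5:
            continue
        sd = past.std(ddof=1)
        if sd == 0:
            continue
        if abs(vols[i] - past.mean()) > k * sd:
            flags.append(dates[i].isoformat())
    return flags


def build_report(pilot: PilotLog, smoothing_window: int = 5,
                 anomaly_k: float = 3.0) -> dict:
    """Structured monitoring report of a pilot run.

    Contains per-week suppression percentage, interacted and order counts
    per arm, the smoothed weekday acceptance curves of each arm, the
    per-arm bulk alerts-per-order ratios, both SNR definitions, the
    one-sided Welch comparisons, and volume anomaly flags.  Every number
    recomputes from the raw pilot events.
    """
    if pilot.events.n_events == 0:
        raise ValueError("empty pilot log")
    weekly = weekly_aggregate(pilot.events, arm_of_date=pilot.arm_of)
    report: dict = {"weekly": weekly.to_dict(orient="records")}

    arms_present = set(weekly["arm"]) if "arm" in weekly else set()
    for arm in ("on", "off"):
        if arm not in arms_present:
            report[f"arm_{arm}"] = {"present": False}
            continue
        wk = weekly.loc[weekly["arm"] == arm]
        alerts = float(wk["alerts"].sum())
        inter = float(wk["interacted"].sum())
        orders = float(wk["orders"].sum())
        arm_rep = {
            "present": True,
            "weeks": int(len(wk)),
            "alerts_total": alerts,
            "interacted_total": inter,
            "orders_total": orders,
            "suppressed_total": float(wk["suppressed"].sum()),
            "appointments_total": float(wk["appointments"].sum()),
            "suppression_pct": 100.0 * float(wk["suppressed"].sum())
            / float(wk["appointments"].sum()),
            "weekly_alert_mean": float(wk["alerts"].mean()),
            "weekly_interacted_mean": float(wk["interacted"].mean()),
            "weekly_order_mean": float(wk["orders"].mean()),
        }
        if orders > 0:
            arm_rep["alerts_per_order_bulk"] = alerts_per_order(alerts,
                                                                orders)
            arm_rep["alerts_per_order_weekly_mean"] = alerts_per_order(
                float(wk["alerts"].mean()), float(wk["orders"].mean()))
            arm_rep["interacted_per_order_bulk"] = inter / orders
        if 0 < orders < alerts:
            arm_rep["snr_orders"] = snr(alerts, None, orders,
                                        "orders_as_signal")
        if 0 < inter < alerts:
            arm_rep["snr_interacted"] = snr(alerts, inter, None,
                                            "interacted_as_signal")
        mask = pilot.events.events["service_date"].dt.date.map(
            lambda d, _arm=arm: (pilot.config.pilot_start <= d
                                 < pilot.config.pilot_end
                                 and pilot.arm_of(d) == _arm))
        arm_log = pilot.events.subset(mask.to_numpy())
        arm_rep["smoothed_daily_acceptance"] = (
            smoothed_daily_rate(arm_log, smoothing_window)
            .assign(date=lambda d: d["date"].dt.date.astype(str))
            .to_dict(orient="records"))
        report[f"arm_{arm}"] = arm_rep

    if (report.get("arm_on", {}).get("present")
            and report.get("arm_off", {}).get("present")):
        on, off = report["arm_on"], report["arm_off"]
        comp = {}
        wk_on = weekly.loc[weekly["arm"] == "on"]
        wk_off = weekly.loc[weekly["arm"] == "off"]
        if len(wk_on) >= 2 and len(wk_off) >= 2:
            for col in ("alerts", "interacted", "orders"):
                res = compare_on_off(wk_on[col], wk_off[col], metric=col)
                comp[col] = {"t": res.t_statistic, "df": res.df,
                             "p_one_sided": res.p_value}
        report["comparisons"] = comp
        report["alert_count_percent_change"] = percent_change(
            off["weekly_alert_mean"], on["weekly_alert_mean"])
        for key in ("snr_orders", "snr_interacted"):
            if key in on and key in off and off[key] > 0:
                report[f"{key}_percent_change"] = percent_change(
                    off[key], on[key])

    daily_all = smoothed_daily_rate(pilot.events, smoothing_window)
    report["anomalies"] = _volume_anomalies(daily_all, k=anomaly_k)
    return report
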