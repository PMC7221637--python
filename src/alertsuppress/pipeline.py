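"""Daily growing-window retraining loop and on/off pilot harness.

Deployment emulation, end to end:

* every day the full alert history from a fixed window start up to (and
  excluding) the run date is refeaturized and the model refit from scratch
  (no warm start);
* clinicians are assigned to train/validation/test folds by a stable hash
  of their id, so fold membership never churns as the window grows or new
  clinicians appear;
* the suppression threshold (default: the 50% suppression fraction) is
  re-derived each day from the updated validation fold's scores;
* next-day *scheduled* appointments are scored with features as of the run
  date; walk-in visits and initial primary-care visits are never
  suppressed and carry an explicit exclusion reason, as does every
  appointment seen during an off week (``model_off``);
* the pilot alternates whole weeks on/off (on-first by default) for six
  weeks; suppressed alerts never fire, so their would-be response is
  erased from the realized log and they are excluded from future training
  rows — the cost of suppression is unobservable in deployment, exactly
  why the off arm exists;
* an append-only run ledger records one row per pilot day (volumes,
  suppression, orders, fatal-error marker).

Off weeks replay the plain simulation stream untouched: with identical
seeds an all-off pilot is byte-identical to no pipeline at all, which is
what makes the two arms comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .alert_log import AlertLog
from .calibration import ThresholdCalibration, select_threshold, \
    tradeoff_curve
from .features import FeatureTable, LabelSpec, build_features
from .model import SuppressionModel, TrainConfig, hash_fold, score, train
from .synthetic_ehr import BehaviorModel, GeneratorConfig, \
    generate_encounters, generate_population, simulate_responses

__all__ = [
    "PipelineConfig",
    "DailyCycleResult",
    "RunLedger",
    "PilotLog",
    "DegenerateHistoryError",
    "daily_cycle",
    "run_pilot",
    "simulate_study",
]

EXCLUSION_REASONS = ("none", "initial_pcp", "walk_in", "model_off")


class DegenerateHistoryError(ValueError):
    """Training history lacks one of the two classes."""


@dataclass(frozen=True)
class PipelineConfig:
    window_start: date = date(2017, 1, 1)
    pilot_start: date = date(2017, 7, 3)     # must be a Monday (ISO weeks)
    pilot_weeks: int = 6
    on_first: bool = True
    calibration_target: float = 0.5
    exclude_initial_pcp: bool = True
    exclude_walk_in: bool = True
    fold_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    train_config: TrainConfig = field(
        default_factory=lambda: TrainConfig(max_rounds=200))
    label_spec: LabelSpec = field(default_factory=LabelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pilot_start.weekday() != 0:
            raise ValueError("pilot_start must be a Monday")
        if self.pilot_weeks < 1:
            raise ValueError("pilot_weeks must be >= 1")
        if not 0.0 <= self.calibration_target <= 1.0:
            raise ValueError("calibration_target outside [0, 1]")

    @property
    def pilot_end(self) -> date:
        """First day after the pilot window."""
        return self.pilot_start + timedelta(weeks=self.pilot_weeks)

    def arm(self, day: date) -> str:
        """'on' or 'off' for a pilot day (whole ISO weeks alternate)."""
        if not self.pilot_start <= day < self.pilot_end:
            raise ValueError(f"{day} outside the pilot window")
        week = (day - self.pilot_start).days // 7
        on = (week % 2 == 0) == self.on_first
        return "on" if on else "off"


@dataclass
class DailyCycleResult:
    model: SuppressionModel | None
    calibration: ThresholdCalibration | None
    decisions: pd.DataFrame


@dataclass
class RunLedger:
    """Append-only per-day run records."""

    records: list[dict] = field(default_factory=list)
    _dates: set = field(default_factory=set, repr=False)

    def append(self, record: dict) -> None:
        day = record["date"]
        if day in self._dates:
            raise ValueError(f"duplicate run record for {day}")
        self._dates.add(day)
        self.records.append(dict(record))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, default=str) + "\n")
        return path


@dataclass
class PilotLog:
    """Realized pilot events + per-alert decisions + run ledger."""

    events: AlertLog
    decisions: pd.DataFrame
    ledger: RunLedger
    config: PipelineConfig
    calibrations: dict[str, ThresholdCalibration] = field(
        default_factory=dict)

    def arm_of(self, day: date) -> str:
        return self.config.arm(day)

    def to_dir(self, path: str | Path) -> Path:
        from .alert_log import write_log
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_log(self.events, path / "events.parquet", "parquet")
        self.decisions.to_parquet(path / "decisions.parquet", index=False)
        self.ledger.to_jsonl(path / "run_ledger.jsonl")
        for day, cal in self.calibrations.items():
            cal.to_json(path / f"calibration_{day}.json")
        (path / "pilot_config.json").write_text(json.dumps(
            asdict(self.config), default=str, indent=2))
        return path


def _empty_decisions() -> pd.DataFrame:
    return pd.DataFrame(columns=["alert_id", "encounter_id",
                                 "decision_date", "score", "threshold",
                                 "suppressed", "exclusion_reason"])


def daily_cycle(run_date: date, history: AlertLog,
                appointments: pd.DataFrame, config: PipelineConfig
                ) -> DailyCycleResult:
    """One production day: refit, recalibrate, decide on tomorrow's visits.

    ``appointments`` is an encounter frame (see
    :func:`alertsuppress.features.encounter_frame`) of next-day visits.
    Only events with ``timestamp`` strictly before ``run_date`` (and on or
    after the window start) are visible for training and features.
    """
    run_ts = pd.Timestamp(run_date)
    ev = history.events
    visible = ((ev["timestamp"] < run_ts)
               & (ev["service_date"] >= pd.Timestamp(config.window_start)))
    hist = history.subset(visible.to_numpy())
    labels = hist.events.loc[hist.events["fired"]]
    if labels.empty:
        raise DegenerateHistoryError("no fired alerts in history")

    table = build_features(hist, config.label_spec)
    folds = table.frame["clinician_id"].map(
        lambda c: hash_fold(c, config.seed, config.fold_fractions))

    def sub(name: str) -> FeatureTable:
        m = (folds == name).to_numpy()
        return FeatureTable(table.frame.loc[m].reset_index(drop=True),
                            encoders=table.encoders, meta=table.meta)

    train_t, val_t = sub("train"), sub("validation")
    if len(train_t) == 0 or train_t.y.nunique() < 2:
        raise DegenerateHistoryError(
            "training fold lacks both classes as of "
            f"{run_date.isoformat()}")
    model = train(train_t, val_t, config=config.train_config,
                  window_end=run_date.isoformat())
    val_scores = score(model, val_t)
    curve = tradeoff_curve(val_scores,
                           val_t.frame["label_interacted"].to_numpy(bool),
                           val_t.frame["label_ordered"].to_numpy(bool),
                           grid=np.linspace(0, 1, 101))
    cal = select_threshold(curve, config.calibration_target,
                           derivation_date=run_date.isoformat())

    if len(appointments) == 0:
        return DailyCycleResult(model, cal, _empty_decisions())

    app = appointments.reset_index(drop=True)
    reason = np.full(len(app), "none", dtype=object)
    if config.exclude_walk_in:
        reason[(app["visit_type"] == "walk_in").to_numpy()] = "walk_in"
    if config.exclude_initial_pcp:
        pcp = app["is_initial_primary_care"].to_numpy(bool)
        reason[(reason == "none") & pcp] = "initial_pcp"

    scores = np.full(len(app), np.nan)
    eligible = reason == "none"
    if eligible.any():
        ft = build_features(hist, config.label_spec,
                            targets=_as_targets(app.loc[eligible]),
                            encoders=table.encoders)
        scores[eligible] = score(model, ft)
    suppressed = eligible & (scores < cal.threshold)

    decisions = pd.DataFrame({
        "alert_id": app["alert_id"].to_numpy(),
        "encounter_id": app["encounter_id"].to_numpy(),
        "decision_date": run_date.isoformat(),
        "score": scores,
        "threshold": cal.threshold,
        "suppressed": suppressed,
        "exclusion_reason": reason,
    })
    return DailyCycleResult(model, cal, decisions)


def _as_targets(app: pd.DataFrame) -> pd.DataFrame:
    cols = ["alert_id", "encounter_id", "patient_id", "clinician_id",
            "service_date", "visit_type", "is_initial_primary_care",
            "clinician_role", "clinician_specialty", "clinician_age_band",
            "clinician_sex", "patient_age", "patient_sex",
            "prior_shingles_vaccine"]
    return app[cols].copy()


def run_pilot(history: AlertLog, pilot_encounters: pd.DataFrame,
              behavior: BehaviorModel, config: PipelineConfig,
              population: tuple[pd.DataFrame, pd.DataFrame] | None = None,
              response_stream: int = 13) -> PilotLog:
    """Simulate the alternating on/off pilot over the configured weeks.

    ``pilot_encounters`` is the appointment stream for the pilot window
    (one row per upcoming alert-eligible encounter).  Responses for every
    encounter are drawn *once*, up front, from the behavior model; on-week
    suppression then erases the draw for withheld alerts.  This makes the
    off arm exchangeable with a pipeline-free simulation under identical
    seeds, and keeps a clinician's counterfactual response independent of
    the suppression decision.
    """
    enc = pilot_encounters.copy()
    enc["service_date"] = pd.to_datetime(enc["service_date"]).dt.normalize()
    start = pd.Timestamp(config.pilot_start)
    end = pd.Timestamp(config.pilot_end)
    if len(enc) and not ((enc["service_date"] >= start)
                         & (enc["service_date"] < end)).all():
        raise ValueError("pilot encounters outside the pilot window")

    counterfactual = simulate_responses(enc, behavior, behavior.config,
                                        population=population,
                                        stream=response_stream)
    cf = counterfactual.events.set_index("encounter_id", drop=False)

    history_frames = [history.events]
    all_decisions = []
    realized_frames = []
    ledger = RunLedger()
    calibrations: dict[str, ThresholdCalibration] = {}

    days = [config.pilot_start + timedelta(days=i)
            for i in range(config.pilot_weeks * 7)]
    for day in days:
        day_ts = pd.Timestamp(day)
        day_enc = enc.loc[enc["service_date"] == day_ts]
        day_app = _with_alert_ids(day_enc, cf)
        arm = config.arm(day)
        fatal = None
        if arm == "off" or len(day_app) == 0:
            decisions = day_app.assign(
                decision_date=(day - timedelta(days=1)).isoformat(),
                score=np.nan, threshold=np.nan, suppressed=False,
                exclusion_reason="model_off",
            )[["alert_id", "encounter_id", "decision_date", "score",
               "threshold", "suppressed", "exclusion_reason"]] \
                if arm == "off" else _empty_decisions()
            suppressed_ids: set = set()
        else:
            hist_log = AlertLog(pd.concat(history_frames,
                                          ignore_index=True))
            result = daily_cycle(day - timedelta(days=1), hist_log,
                                 day_app, config)
            decisions = result.decisions
            calibrations[day.isoformat()] = result.calibration
            suppressed_ids = set(
                decisions.loc[decisions["suppressed"], "encounter_id"])

        day_events = cf.loc[cf["service_date"] == day_ts].copy()
        if suppressed_ids:
            m = day_events["encounter_id"].isin(suppressed_ids)
            day_events.loc[m, "fired"] = False
            day_events.loc[m, "suppressed"] = True
            day_events.loc[m, "response_action"] = "none"
            day_events.loc[m, "order_placed"] = False
        realized_frames.append(day_events.reset_index(drop=True))
        history_frames.append(day_events.reset_index(drop=True))
        all_decisions.append(decisions)

        fired = day_events["fired"]
        ledger.append({
            "date": day.isoformat(),
            "arm": arm,
            "n_appointments": int(len(day_events)),
            "n_suppressed": int(day_events["suppressed"].sum()),
            "suppression_pct": (100.0 * day_events["suppressed"].sum()
                                / len(day_events)
                                if len(day_events) else 0.0),
            "n_fired": int(fired.sum()),
            "n_interacted": int((fired & (day_events["response_action"]
                                          != "none")).sum()),
            "n_orders": int(day_events["order_placed"].sum()),
            "fatal_error": fatal,
        })

    events = AlertLog(pd.concat(realized_frames, ignore_index=True)
                      if realized_frames else counterfactual.events.iloc[:0])
    decisions = (pd.concat(all_decisions, ignore_index=True)
                 if all_decisions else _empty_decisions())
    return PilotLog(events=events, decisions=decisions, ledger=ledger,
                    config=config, calibrations=calibrations)


def _with_alert_ids(day_enc: pd.DataFrame, cf: pd.DataFrame) -> pd.DataFrame:
    """Attach the (pre-drawn) alert ids and static attributes."""
    if len(day_enc) == 0:
        return cf.iloc[:0][["alert_id", "encounter_id", "patient_id",
                            "clinician_id", "service_date", "visit_type",
                            "is_initial_primary_care", "clinician_role",
                            "clinician_specialty", "clinician_age_band",
                            "clinician_sex", "patient_age", "patient_sex",
                            "prior_shingles_vaccine"]].copy()
    sub = cf.loc[day_enc["encounter_id"]]
    return sub[["alert_id", "encounter_id", "patient_id", "clinician_id",
                "service_date", "visit_type", "is_initial_primary_care",
                "clinician_role", "clinician_specialty",
                "clinician_age_band", "clinician_sex", "patient_age",
                "patient_sex", "prior_shingles_vaccine"]].reset_index(
                    drop=True)


def simulate_study(gen_config: GeneratorConfig, config: PipelineConfig
                   ) -> PilotLog:
    """Convenience: synthesize history + pilot stream, then run the pilot.

    The generator's date range is treated as the history window; pilot
    encounters are drawn for the pilot window with the same population and
    behavior.
    """
    from dataclasses import replace
    from .synthetic_ehr import calibrate_behavior

    population = generate_population(gen_config)
    behavior = calibrate_behavior(gen_config)
    hist_enc = generate_encounters(population, gen_config)
    history = simulate_responses(hist_enc, behavior, gen_config, population)

    # Same cohort and behavior; only the date range moves to the pilot
    # window.  Dedicated streams keep pilot draws independent of history.
    pilot_cfg = replace(gen_config,
                        date_range=(config.pilot_start,
                                    config.pilot_end - timedelta(days=1)))
    pilot_enc = generate_encounters(population, pilot_cfg, stream=12)
    pilot_enc["encounter_id"] = "EP" + pilot_enc["encounter_id"].str[1:]
    return run_pilot(history, pilot_enc, behavior, config,
                     population=population, response_stream=13)
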