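"""Leakage-safe activity-history features and labels.

Each alert-eligible encounter becomes one feature row.  Its ``as_of``
timestamp is the day *before* the encounter date (the deployment scores
tomorrow's appointments with data available today), and every history
feature is computed from fired alert events with ``timestamp < as_of`` —
strictly earlier, so neither same-day events nor the scoring day itself
can leak into the features.

Clinician activity history (the dominant signal):

* short-term response rate — interactions / alerts over the trailing
  1-month (30-day) window ending at ``as_of``;
* long-term response rate — over the clinician's full prior history;
* recent encounter count — the clinician's alert-eligible encounters in
  the trailing 30 days (suppressed alerts still count as encounters: the
  visit happened whether or not its alert fired);
* lifetime prior alert count.

Patient history: counts of prior alerts shown, prior interactions, and
prior vaccine orders for that patient, plus demographics and the
prior-vaccination flag.  Visit features: the walk-in flag.

A clinician or patient with no usable history gets NaN rates — a dedicated
missing sentinel passed natively to the tree model rather than imputed, so
"no history" stays visible as signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .alert_log import AlertLog, interaction_mask

__all__ = [
    "LabelSpec",
    "FeatureTable",
    "SHORT_WINDOW_DAYS",
    "FEATURE_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "assign_provider",
    "build_features",
    "build_labels",
    "encounter_frame",
]

SHORT_WINDOW_DAYS = 30

CATEGORICAL_COLUMNS = ["clin_role", "clin_specialty", "clin_age_band",
                       "clin_sex", "pat_sex"]

FEATURE_COLUMNS = CATEGORICAL_COLUMNS + [
    "clin_short_rate", "clin_long_rate", "clin_short_n", "clin_long_n",
    "clin_recent_encounters",
    "pat_age", "pat_prior_alerts", "pat_prior_interactions",
    "pat_prior_orders", "pat_prior_vaccine",
    "walk_in",
]


@dataclass(frozen=True)
class LabelSpec:
    """Binary-target definition: interacted-or-ordered (default) or
    ordered-only.  Since an order requires opening the order set, the
    default label reduces to the interaction flag."""

    definition: Literal["interacted_or_ordered", "ordered_only"] = (
        "interacted_or_ordered")


@dataclass
class FeatureTable:
    """Feature matrix plus sidecar metadata (windows, encoder maps)."""

    frame: pd.DataFrame
    encoders: dict[str, dict[str, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[FEATURE_COLUMNS]

    @property
    def y(self) -> pd.Series:
        return self.frame["label"]

    def __len__(self) -> int:
        return len(self.frame)


def assign_provider(records: pd.DataFrame) -> pd.Series:
    """Pick the one provider responsible for each alert encounter.

    ``records`` has one row per (encounter_id, clinician_id) raw alert
    record with boolean ``interacted`` and ``timestamp`` columns.  The
    winner per encounter is the clinician with the most interactions,
    ties broken by earliest action timestamp, then lexicographically
    smallest clinician_id.  Returns a Series encounter_id -> clinician_id.
    """
    if records.empty:
        return pd.Series(dtype=object, name="clinician_id")
    if records["clinician_id"].isna().any():
        enc = records.loc[records["clinician_id"].isna(),
                          "encounter_id"].iloc[0]
        raise ValueError(f"encounter {enc!r} has no clinician record")
    grp = (records.groupby(["encounter_id", "clinician_id"])
           .agg(n_inter=("interacted", "sum"), first_ts=("timestamp", "min"))
           .reset_index())
    n_enc = grp["encounter_id"].nunique()
    if records["encounter_id"].isna().any():
        raise ValueError("encounter with missing id")
    grp = grp.sort_values(
        ["encounter_id", "n_inter", "first_ts", "clinician_id"],
        ascending=[True, False, True, True], kind="mergesort")
    out = grp.drop_duplicates("encounter_id").set_index("encounter_id")
    assert len(out) == n_enc
    return out["clinician_id"]


def build_labels(log: AlertLog, spec: LabelSpec = LabelSpec()) -> pd.Series:
    """Binary target per fired alert event (index = alert_id)."""
    ev = log.events
    if spec.definition == "ordered_only":
        lab = ev["order_placed"]
    else:
        lab = interaction_mask(ev) | ev["order_placed"]
    return pd.Series(lab.to_numpy(int), index=ev["alert_id"], name="label")


def encounter_frame(log: AlertLog) -> pd.DataFrame:
    """Encounter-level view of a log (for scoring upcoming appointments)."""
    cols = ["alert_id", "encounter_id", "patient_id", "clinician_id",
            "service_date", "visit_type", "is_initial_primary_care",
            "clinician_role", "clinician_specialty", "clinician_age_band",
            "clinician_sex", "patient_age", "patient_sex",
            "prior_shingles_vaccine"]
    return log.events[cols].copy()


def _history_counts(history: pd.DataFrame, key: str,
                    targets: pd.DataFrame,
                    short_window_days: int = SHORT_WINDOW_DAYS
                    ) -> dict[str, np.ndarray]:
    """Trailing-window counts per target row, strictly before its as_of.

    For every target row, counts of the keyed entity's prior fired alerts,
    interactions and orders over the full history and the trailing short
    window.  Fully vectorized: entities and timestamps are combined into a
    single sortable composite key so one searchsorted per bound serves all
    rows, with global prefix sums supplying the counts.
    """
    n = len(targets)
    out = {k: np.zeros(n) for k in
           ("long_n", "long_k", "short_n", "short_k", "orders")}
    if len(history) == 0:
        return out
    as_of = targets["as_of"].to_numpy("datetime64[ns]")
    win_start = (targets["as_of"]
                 - pd.Timedelta(days=short_window_days)).to_numpy(
                     "datetime64[ns]")

    codes, uniques = pd.factorize(history[key], sort=False)
    tgt_codes = (pd.Index(uniques)
                 .get_indexer(targets[key]))  # -1 for unseen entities
    hist_ts = history["timestamp"].to_numpy("datetime64[ns]")
    # Dense time ranks keep the composite key within int64.
    all_ts = np.unique(hist_ts)
    m = len(all_ts) + 1
    hist_key = codes.astype(np.int64) * m + np.searchsorted(all_ts, hist_ts)
    order = np.argsort(hist_key, kind="stable")
    sorted_key = hist_key[order]
    cum_inter = np.concatenate(
        [[0], np.cumsum(history["_inter"].to_numpy(int)[order])])
    cum_orders = np.concatenate(
        [[0], np.cumsum(history["order_placed"].to_numpy(int)[order])])

    seen = tgt_codes >= 0
    tc = tgt_codes[seen].astype(np.int64)
    hi_rank = np.searchsorted(all_ts, as_of[seen], side="left")
    lo_rank = np.searchsorted(all_ts, win_start[seen], side="left")
    start = np.searchsorted(sorted_key, tc * m)
    hi = np.searchsorted(sorted_key, tc * m + hi_rank, side="left")
    lo = np.searchsorted(sorted_key, tc * m + lo_rank, side="left")

    out["long_n"][seen] = hi - start
    out["long_k"][seen] = cum_inter[hi] - cum_inter[start]
    out["short_n"][seen] = hi - lo
    out["short_k"][seen] = cum_inter[hi] - cum_inter[lo]
    out["orders"][seen] = cum_orders[hi] - cum_orders[start]
    return out


def build_features(log: AlertLog, spec: LabelSpec = LabelSpec(),
                   targets: pd.DataFrame | None = None,
                   encoders: dict[str, dict[str, int]] | None = None,
                   short_window_days: int = SHORT_WINDOW_DAYS,
                   ) -> FeatureTable:
    """Build one leakage-safe feature row per target encounter.

    By default every *fired* event of ``log`` is both history and target
    (retrospective training mode).  Passing an explicit ``targets``
    encounter frame (see :func:`encounter_frame`) scores arbitrary —
    possibly future — appointments against the log's history; target rows
    then carry no labels.

    History is restricted to fired events: a suppressed alert was never
    shown, so it contributes neither alert exposures nor responses.
    """
    ev = log.events
    cols = ["clinician_id", "patient_id", "timestamp", "order_placed"]
    history = ev.loc[ev["fired"], cols].copy()
    history["_inter"] = interaction_mask(ev)[ev["fired"]].to_numpy()
    # Exposure counts include suppressed events: the encounter happened
    # and is in the record whether or not its alert fired.
    exposures = ev[cols].copy()
    exposures["_inter"] = interaction_mask(ev).to_numpy()

    if targets is None:
        targets = encounter_frame(log.subset(ev["fired"].to_numpy()))
        labels = build_labels(log.subset(ev["fired"].to_numpy()), spec)
    else:
        targets = targets.copy()
        labels = None
    targets = targets.reset_index(drop=True)
    targets["service_date"] = pd.to_datetime(
        targets["service_date"]).dt.normalize()
    targets["as_of"] = targets["service_date"] - pd.Timedelta(days=1)

    clin = _history_counts(history, "clinician_id", targets,
                           short_window_days)
    clin_exp = _history_counts(exposures, "clinician_id", targets,
                               short_window_days)
    pat = _history_counts(history, "patient_id", targets, short_window_days)

    with np.errstate(invalid="ignore", divide="ignore"):
        short_rate = np.where(clin["short_n"] > 0,
                              clin["short_k"] / clin["short_n"], np.nan)
        long_rate = np.where(clin["long_n"] > 0,
                             clin["long_k"] / clin["long_n"], np.nan)

    frame = pd.DataFrame({
        "alert_id": targets["alert_id"].to_numpy(),
        "encounter_id": targets["encounter_id"].to_numpy(),
        "clinician_id": targets["clinician_id"].to_numpy(),
        "patient_id": targets["patient_id"].to_numpy(),
        "as_of": targets["as_of"].to_numpy(),
        "service_date": targets["service_date"].to_numpy(),
        "clin_role": targets["clinician_role"].to_numpy(),
        "clin_specialty": targets["clinician_specialty"].to_numpy(),
        "clin_age_band": targets["clinician_age_band"].to_numpy(),
        "clin_sex": targets["clinician_sex"].to_numpy(),
        "pat_sex": targets["patient_sex"].to_numpy(),
        "clin_short_rate": short_rate,
        "clin_long_rate": long_rate,
        "clin_short_n": clin["short_n"],
        "clin_long_n": clin["long_n"],
        "clin_recent_encounters": clin_exp["short_n"],
        "pat_age": targets["patient_age"].to_numpy(float),
        "pat_prior_alerts": pat["long_n"],
        "pat_prior_interactions": pat["long_k"],
        "pat_prior_orders": pat["orders"],
        "pat_prior_vaccine":
            targets["prior_shingles_vaccine"].to_numpy(float),
        "walk_in": (targets["visit_type"] == "walk_in").to_numpy(float),
    })
    if labels is not None:
        fired = log.subset(ev["fired"].to_numpy())
        fired_ev = fired.events.set_index("alert_id")
        frame["label_interacted"] = (
            interaction_mask(fired_ev).reindex(frame["alert_id"])
            .to_numpy(int))
        frame["label_ordered"] = (
            fired_ev["order_placed"].reindex(frame["alert_id"])
            .to_numpy(int))
        frame["label"] = labels.reindex(frame["alert_id"]).to_numpy()

    encoders = _encode_categoricals(frame, encoders)
    meta = {"short_window_days": short_window_days,
            "long_window": "full history",
            "as_of_rule": "day before service_date; events strictly earlier",
            "label_definition": spec.definition,
            "feature_columns": FEATURE_COLUMNS}
    return FeatureTable(frame=frame, encoders=encoders, meta=meta)


def _encode_categoricals(frame: pd.DataFrame,
                         encoders: dict[str, dict[str, int]] | None
                         ) -> dict[str, dict[str, int]]:
    """Integer-encode categorical columns in place; unseen values -> NaN.

    When ``encoders`` is given (scoring with a persisted model) its maps
    are reused; otherwise fresh maps are fit on the frame.
    """
    fit = encoders is None
    encoders = {} if fit else dict(encoders)
    for col in CATEGORICAL_COLUMNS:
        if fit:
            cats = sorted(pd.unique(frame[col].astype(str)))
            encoders[col] = {c: i for i, c in enumerate(cats)}
        frame[col] = frame[col].astype(str).map(encoders[col]).astype(float)
    return encoders
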