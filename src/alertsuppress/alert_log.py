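"""Canonical alert-log data model and file I/O.

The atom of every computation is one best-practice-advisory (BPA) alert
instance tied to an outpatient encounter.  The log is stored as a single
wide, denormalized table — one row per alert event carrying its encounter,
clinician, and patient attributes — which is the authoritative on-disk
representation (CSV or Parquet).  A JSON schema describing the table ships
with the package under ``alertsuppress/schemas/``.

An alert either fires (is shown to the clinician) or is suppressed.  A fired
alert receives one of four response actions: opening the order set
(``open_smartset``, through which a vaccine order may be signed), an
``override``, a ``postpone``, or ``none`` when the alert is ignored or
closed without action.  "Interaction" means any action other than ``none``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_ACTIONS",
    "VISIT_TYPES",
    "CLINICIAN_ROLES",
    "WIDE_COLUMNS",
    "SchemaViolationError",
    "IntegrityError",
    "AlertLog",
    "read_log",
    "write_log",
    "interaction_flag",
    "interaction_mask",
    "load_schema",
]

RESPONSE_ACTIONS = ("open_smartset", "override", "postpone", "none")
VISIT_TYPES = ("scheduled", "walk_in")
CLINICIAN_ROLES = ("physician", "advanced_practice", "nurse", "other")

#: Column -> dtype kind of the authoritative wide table.
WIDE_COLUMNS: dict[str, str] = {
    "alert_id": "string",
    "encounter_id": "string",
    "patient_id": "string",
    "clinician_id": "string",
    "timestamp": "datetime",
    "service_date": "date",
    "visit_type": "category",
    "is_initial_primary_care": "bool",
    "clinician_role": "category",
    "clinician_specialty": "string",
    "clinician_age_band": "string",
    "clinician_sex": "string",
    "patient_age": "int",
    "patient_sex": "string",
    "prior_shingles_vaccine": "bool",
    "fired": "bool",
    "suppressed": "bool",
    "response_action": "category",
    "order_placed": "bool",
}

_BOOL_COLS = [c for c, k in WIDE_COLUMNS.items() if k == "bool"]


class SchemaViolationError(ValueError):
    """A file or frame does not conform to the wide alert-log schema."""


class IntegrityError(ValueError):
    """A record violates a cross-field or cross-row invariant."""


def load_schema() -> dict:
    """Return the packaged JSON schema of the wide table."""
    with resources.files("alertsuppress.schemas").joinpath(
        "alert_log_schema.json"
    ).open() as fh:
        return json.load(fh)


@dataclass
class AlertLog:
    """A validated collection of alert events, sorted by timestamp.

    Parameters
    ----------
    events
        Wide table with the columns of :data:`WIDE_COLUMNS`.
    clinicians, patients
        Optional normalized side tables.  The wide table is authoritative;
        when present the side tables are only checked for referential
        integrity.  Generator-side clinician tables may carry the latent
        response propensity; that column never appears in the wide table.
    """

    events: pd.DataFrame
    clinicians: pd.DataFrame | None = field(default=None, repr=False)
    patients: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.events = _coerce(self.events)
        self.validate()
        self.events = (
            self.events.sort_values(["timestamp", "alert_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    # ------------------------------------------------------------------ counts
    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_fired(self) -> int:
        return int(self.events["fired"].sum())

    @property
    def n_interactions(self) -> int:
        return int(interaction_mask(self.events).sum())

    @property
    def n_orders(self) -> int:
        return int(self.events["order_placed"].sum())

    @property
    def n_suppressed(self) -> int:
        return int(self.events["suppressed"].sum())

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        ev = self.events
        missing = [c for c in WIDE_COLUMNS if c not in ev.columns]
        if missing:
            raise SchemaViolationError(f"missing column(s): {missing}")

        for col, allowed in (
            ("response_action", RESPONSE_ACTIONS),
            ("visit_type", VISIT_TYPES),
            ("clinician_role", CLINICIAN_ROLES),
        ):
            bad = ~ev[col].isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaViolationError(
                    f"column {col!r}, row {row}: value "
                    f"{ev[col].iloc[row]!r} not in {allowed}"
                )

        if ev["alert_id"].duplicated().any():
            dup = ev.loc[ev["alert_id"].duplicated(), "alert_id"].iloc[0]
            raise IntegrityError(f"duplicate alert_id {dup!r}")
        if ev["encounter_id"].duplicated().any():
            dup = ev.loc[ev["encounter_id"].duplicated(), "encounter_id"].iloc[0]
            raise IntegrityError(
                f"encounter {dup!r} has more than one alert event"
            )
        if (ev["patient_age"] < 0).any():
            raise SchemaViolationError("patient_age must be >= 0")

        # Causal chain: suppressed => not fired => no action, no order.
        bad = ev["suppressed"] & ev["fired"]
        if bad.any():
            raise IntegrityError(
                f"alert {ev.loc[bad, 'alert_id'].iloc[0]!r} both "
                "suppressed and fired"
            )
        unfired = ~ev["fired"]
        bad = unfired & (ev["response_action"] != "none")
        if bad.any():
            raise IntegrityError(
                f"unfired alert {ev.loc[bad, 'alert_id'].iloc[0]!r} "
                "has a response action"
            )
        bad = unfired & ev["order_placed"]
        if bad.any():
            raise IntegrityError(
                f"unfired alert {ev.loc[bad, 'alert_id'].iloc[0]!r} "
                "has an order"
            )
        bad = ev["order_placed"] & (ev["response_action"] != "open_smartset")
        if bad.any():
            raise IntegrityError(
                f"alert {ev.loc[bad, 'alert_id'].iloc[0]!r}: order placed "
                "without opening the order set"
            )

        for side, key in ((self.clinicians, "clinician_id"),
                          (self.patients, "patient_id")):
            if side is not None:
                dangling = ~ev[key].isin(side[key])
                if dangling.any():
                    raise IntegrityError(
                        f"dangling {key} {ev.loc[dangling, key].iloc[0]!r}"
                    )

    # --------------------------------------------------------------- utilities
    def subset(self, mask: pd.Series | np.ndarray) -> "AlertLog":
        """A new log restricted to rows where ``mask`` holds."""
        return AlertLog(self.events.loc[mask].copy(),
                        clinicians=self.clinicians, patients=self.patients)

    def __len__(self) -> int:
        return len(self.events)


def _coerce(ev: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw frame to canonical dtypes (shared by reader and ctor)."""
    ev = ev.copy()
    missing = [c for c in WIDE_COLUMNS if c not in ev.columns]
    if missing:
        raise SchemaViolationError(f"missing column(s): {missing}")
    try:
        ev["timestamp"] = pd.to_datetime(ev["timestamp"])
        ev["service_date"] = pd.to_datetime(ev["service_date"]).dt.normalize()
        ev["patient_age"] = ev["patient_age"].astype("int64")
        for c in _BOOL_COLS:
            if ev[c].dtype == object:  # CSV round-trip may yield strings
                ev[c] = ev[c].map({"True": True, "False": False,
                                   True: True, False: False})
            ev[c] = ev[c].astype(bool)
        for c, kind in WIDE_COLUMNS.items():
            if kind in ("string", "category"):
                ev[c] = ev[c].astype(str)
    except (ValueError, TypeError) as exc:
        raise SchemaViolationError(f"cannot coerce column types: {exc}") from exc
    return ev


def interaction_flag(event) -> bool:
    """Whether a single fired alert received any acknowledging action.

    Any action toward acknowledging the alert — opening the order set,
    overriding, or postponing — counts; ignoring/closing (``none``) does not.
    """
    if not bool(event["fired"]):
        raise ValueError("interaction is defined only for fired alerts")
    return event["response_action"] != "none"


def interaction_mask(events: pd.DataFrame) -> pd.Series:
    """Vectorized interaction indicator (False for unfired rows)."""
    return events["fired"] & (events["response_action"] != "none")


def write_log(log: AlertLog, path: str | Path, dialect: str = "parquet") -> Path:
    """Serialize the wide table; round-trips field-for-field via read_log."""
    path = Path(path)
    ev = log.events.copy()
    ev["service_date"] = ev["service_date"].dt.strftime("%Y-%m-%d")
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    if dialect == "csv":
        ev.to_csv(path, index=False)
    elif dialect == "parquet":
        ev.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_log(path: str | Path, dialect: str = "parquet") -> AlertLog:
    """Read and validate a wide-table alert log.

    Raises
    ------
    SchemaViolationError
        Malformed file, wrong dialect, missing or ill-typed columns.
    IntegrityError
        Duplicate ids or causal-chain violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if dialect == "csv":
            ev = pd.read_csv(path, dtype={"alert_id": str, "encounter_id": str,
                                          "patient_id": str, "clinician_id": str})
        elif dialect == "parquet":
            ev = pd.read_parquet(path)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise SchemaViolationError(
            f"{path} cannot be parsed as {dialect}: {exc}"
        ) from exc
    if len(ev) == 0 and list(ev.columns):  # header-only file
        ev = ev.reindex(columns=list(WIDE_COLUMNS))
    return AlertLog(ev)


def concat_logs(logs: Iterable[AlertLog]) -> AlertLog:
    """Concatenate logs into one (invariants re-validated)."""
    frames = [lg.events for lg in logs]
    return AlertLog(pd.concat(frames, ignore_index=True))
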