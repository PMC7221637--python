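"""Suppression-threshold derivation and its cost/benefit accounting.

The operating point is a *suppression fraction* q: the q lowest-scoring
validation alerts would be withheld.  The score threshold is the empirical
lower (type-1) quantile of validation scores — always an observed score —
and suppression uses strict inequality (score < threshold).  Together
these guarantee the realized suppressed fraction on the derivation set
never exceeds q, even with tied scores, and equals floor(q·n)/n when all
scores are distinct.

Cost/benefit per candidate q:

* ignored-among-suppressed — fraction of would-be-suppressed alerts that
  the clinician would have ignored anyway (the benefit: pure noise
  removed);
* order reduction — vaccine orders lost to suppression as a fraction of
  all alerts (so at q=1 it equals the set's overall order rate);
* orders-among-suppressed and orders-lost/total-orders are also reported.

A nested clinician-level cross-validation estimates the out-of-sample
order reduction of a chosen q: within each outer fold the threshold is
derived on an inner 80/20 split and charged against the untouched outer
fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable
from .model import TrainConfig, train, score

__all__ = [
    "TradeoffCurve",
    "ThresholdCalibration",
    "SuppressionSummary",
    "quantile_threshold",
    "tradeoff_curve",
    "select_threshold",
    "simulate_suppression",
    "estimate_order_reduction",
]


def quantile_threshold(scores: np.ndarray, q: float) -> float:
    """Lower-quantile score cutoff for suppression fraction ``q``.

    Returns the order statistic at rank floor(q·n) (0-based), so that
    strictly-below-threshold suppression withholds at most floor(q·n)
    rows; ``q == 1`` returns +inf (suppress everything).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"target fraction {q} outside [0, 1]")
    s = np.sort(np.asarray(scores, float))
    n = len(s)
    if n == 0:
        raise ValueError("empty score set")
    k = int(np.floor(q * n))
    if k >= n:
        return float("inf")
    return float(s[k])


@dataclass
class TradeoffCurve:
    """Grid of candidate suppression fractions with their costs/benefits.

    Retains the raw score/label vectors so any off-grid target can be
    recalibrated exactly."""

    frame: pd.DataFrame
    scores: np.ndarray = field(repr=False)
    interacted: np.ndarray = field(repr=False)
    ordered: np.ndarray = field(repr=False)


@dataclass
class ThresholdCalibration:
    target_fraction: float
    threshold: float
    est_suppressed_fraction: float
    est_ignored_among_suppressed: float
    est_order_reduction: float
    derivation_date: str | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdCalibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SuppressionSummary:
    n: int
    n_suppressed: int
    n_ignored_suppressed: int
    n_orders_suppressed: int
    pct_suppressed: float
    pct_ignored_among_suppressed: float
    pct_order_reduction: float
    pct_orders_lost: float  # suppressed orders / total orders


def _checked(scores, interacted, ordered):
    scores = np.asarray(scores, float)
    interacted = np.asarray(interacted, bool)
    ordered = np.asarray(ordered, bool)
    if not (len(scores) == len(interacted) == len(ordered)):
        raise ValueError(
            f"misaligned lengths: {len(scores)}, {len(interacted)}, "
            f"{len(ordered)}")
    if len(scores) == 0:
        raise ValueError("empty inputs")
    return scores, interacted, ordered


def tradeoff_curve(scores, interacted, ordered,
                   grid: np.ndarray | None = None) -> TradeoffCurve:
    """Evaluate every candidate suppression fraction on aligned vectors."""
    scores, interacted, ordered = _checked(scores, interacted, ordered)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    n = len(scores)
    rows = []
    for q in grid:
        thr = quantile_threshold(scores, float(q))
        sup = scores < thr
        ns = int(sup.sum())
        rows.append({
            "q": float(q),
            "threshold": thr,
            "n_suppressed": ns,
            "suppressed_fraction": ns / n,
            "ignored_among_suppressed":
                float((~interacted[sup]).mean()) if ns else np.nan,
            "orders_among_suppressed":
                float(ordered[sup].mean()) if ns else np.nan,
            "order_reduction": float(ordered[sup].sum()) / n,
        })
    return TradeoffCurve(frame=pd.DataFrame(rows), scores=scores,
                         interacted=interacted, ordered=ordered)


def select_threshold(curve: TradeoffCurve, target_fraction: float = 0.5,
                     derivation_date: str | None = None
                     ) -> ThresholdCalibration:
    """Derive the operating threshold for a target suppression fraction."""
    thr = quantile_threshold(curve.scores, target_fraction)
    sup = curve.scores < thr
    ns = int(sup.sum())
    n = len(curve.scores)
    return ThresholdCalibration(
        target_fraction=float(target_fraction),
        threshold=thr,
        est_suppressed_fraction=ns / n,
        est_ignored_among_suppressed=(
            float((~curve.interacted[sup]).mean()) if ns else 0.0),
        est_order_reduction=float(curve.ordered[sup].sum()) / n,
        derivation_date=derivation_date,
    )


def simulate_suppression(scores, interacted, ordered,
                         calibration: ThresholdCalibration
                         ) -> SuppressionSummary:
    """Retrospective what-if: apply a calibrated threshold to scored rows."""
    scores, interacted, ordered = _checked(scores, interacted, ordered)
    sup = scores < calibration.threshold
    n, ns = len(scores), int(sup.sum())
    n_ign = int((~interacted[sup]).sum())
    n_ord = int(ordered[sup].sum())
    total_orders = int(ordered.sum())
    return SuppressionSummary(
        n=n, n_suppressed=ns, n_ignored_suppressed=n_ign,
        n_orders_suppressed=n_ord,
        pct_suppressed=100.0 * ns / n,
        pct_ignored_among_suppressed=100.0 * n_ign / ns if ns else 0.0,
        pct_order_reduction=100.0 * n_ord / n,
        pct_orders_lost=(100.0 * n_ord / total_orders
                         if total_orders else 0.0),
    )


def estimate_order_reduction(table: FeatureTable, k: int = 5,
                             target_fraction: float = 0.5,
                             config: TrainConfig = TrainConfig(),
                             seed: int = 0) -> float:
    """Nested-CV estimate of order reduction at a suppression fraction.

    Outer: k clinician-level folds.  Inner: 80/20 clinician split of the
    outer-training clinicians; the model is fitted on the inner-train
    rows, the threshold derived from inner-validation scores, and the
    order reduction measured on the untouched outer fold.  Returns the
    mean outer-fold order reduction (fraction of outer rows whose order
    would be lost).
    """
    frame = table.frame
    clinicians = np.array(sorted(frame["clinician_id"].unique()))
    if len(clinicians) < k:
        raise ValueError(f"need >= {k} clinicians")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(clinicians)
    folds = np.array_split(perm, k)
    out = []
    for i, held in enumerate(folds):
        held = set(held)
        rest = [c for c in perm if c not in held]
        n_fit = max(1, int(round(0.8 * len(rest))))
        fit_ids, val_ids = set(rest[:n_fit]), set(rest[n_fit:])

        def sub(ids):
            m = frame["clinician_id"].isin(ids).to_numpy()
            return FeatureTable(frame.loc[m].reset_index(drop=True),
                                encoders=table.encoders, meta=table.meta)

        model = train(sub(fit_ids), sub(val_ids), config=config)
        val = sub(val_ids)
        thr = quantile_threshold(score(model, val), target_fraction)
        outer = sub(held)
        s = score(model, outer)
        sup = s < thr
        ordered = outer.frame["label_ordered"].to_numpy(bool)
        lost = float(ordered[sup].sum()) / len(outer)
        out.append(lost)
    return float(np.mean(out))
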