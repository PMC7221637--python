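"""Gradient-boosted interaction classifier.

Binary target: will this alert be interacted with (or followed by an
order)?  Training protocol:

* clinician-level 80/10/10 train/validation/test split — all of a
  clinician's rows land in one fold, so a provider's identity can never
  leak across folds;
* XGBoost with learning rate 0.3, maximum tree depth 6, minimum child
  weight 1, no row or column subsampling, logistic loss monitored as log
  loss on the validation fold, and early stopping with a 50-round patience
  (up to 1000 boosting rounds);
* NaN feature values (the missing-history sentinel) are routed natively by
  the trees;
* 5-fold clinician-level cross-validation reporting AUROC and area under
  the precision-recall curve.

No class reweighting is applied to the ~16%-positive imbalance by default;
``scale_pos_weight`` is exposed for experimentation.  Model artifacts are
persisted as a directory holding the booster (JSON) plus a metadata file
with the feature columns, encoder maps, and training-window end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import FEATURE_COLUMNS, FeatureTable

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "SuppressionModel",
    "CvReport",
    "split_by_clinician",
    "hash_fold",
    "train",
    "score",
    "cross_validate",
]


@dataclass(frozen=True)
class SplitSpec:
    """Clinician-level fold fractions (train, validation, test)."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be nonnegative")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.3
    max_tree_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    early_stopping_rounds: int = 50
    max_rounds: int = 1000
    scale_pos_weight: float = 1.0
    seed: int = 0
    nthread: int = 1

    def __post_init__(self) -> None:
        if (self.learning_rate <= 0 or self.max_tree_depth <= 0
                or self.min_child_weight <= 0 or self.max_rounds <= 0
                or not 0 < self.subsample <= 1
                or not 0 < self.colsample_bytree <= 1):
            raise ValueError("hyperparameters must be positive")

    def xgb_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "logloss",
            "eta": self.learning_rate,
            "max_depth": self.max_tree_depth,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "scale_pos_weight": self.scale_pos_weight,
            "seed": self.seed,
            "nthread": self.nthread,
            "tree_method": "hist",
        }


@dataclass
class SuppressionModel:
    """A fitted booster plus everything needed to score consistently."""

    booster: xgb.Booster
    feature_columns: list[str]
    encoders: dict[str, dict[str, int]]
    best_iteration: int
    train_config: TrainConfig
    window_end: str | None = None
    eval_history: dict = field(default_factory=dict, repr=False)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(path / "booster.json")
        meta = {
            "feature_columns": self.feature_columns,
            "encoders": self.encoders,
            "best_iteration": self.best_iteration,
            "train_config": asdict(self.train_config),
            "window_end": self.window_end,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(self.train_config),
                           sort_keys=True).encode()).hexdigest()[:16],
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SuppressionModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path / "booster.json")
        meta = json.loads((path / "meta.json").read_text())
        return cls(booster=booster,
                   feature_columns=meta["feature_columns"],
                   encoders=meta["encoders"],
                   best_iteration=meta["best_iteration"],
                   train_config=TrainConfig(**meta["train_config"]),
                   window_end=meta["window_end"])


@dataclass
class CvReport:
    auroc: list[float]
    auprc: list[float]

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.auprc))


def split_by_clinician(table: FeatureTable, spec: SplitSpec = SplitSpec()
                       ) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Partition rows into train/validation/test by clinician.

    Exact fold sizes: with n clinicians the validation and test folds get
    max(1, floor(fraction * n)) clinicians each, the rest train.
    """
    clinicians = np.array(sorted(table.frame["clinician_id"].unique()))
    n = len(clinicians)
    if n < 3:
        raise ValueError(f"need >= 3 clinicians, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(clinicians)
    f_tr, f_va, f_te = spec.fractions
    n_va = max(1, int(np.floor(f_va * n)))
    n_te = max(1, int(np.floor(f_te * n)))
    va = set(perm[:n_va])
    te = set(perm[n_va:n_va + n_te])

    def pick(which: set) -> FeatureTable:
        mask = table.frame["clinician_id"].isin(which).to_numpy()
        return FeatureTable(table.frame.loc[mask].reset_index(drop=True),
                            encoders=table.encoders, meta=table.meta)

    tr = set(perm[n_va + n_te:])
    return pick(tr), pick(va), pick(te)


def hash_fold(clinician_id: str, seed: int = 0,
              fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> str:
    """Stable hash-based fold assignment ("train"/"validation"/"test").

    Used by the daily retraining loop: a clinician's fold never changes as
    the dataset grows or new clinicians appear.
    """
    h = hashlib.sha256(f"{seed}:{clinician_id}".encode()).digest()
    u = int.from_bytes(h[:8], "big") / 2 ** 64
    if u < fractions[0]:
        return "train"
    if u < fractions[0] + fractions[1]:
        return "validation"
    return "test"


def _dmatrix(table: FeatureTable, columns: list[str]) -> xgb.DMatrix:
    X = table.frame.reindex(columns=columns)
    y = table.frame["label"] if "label" in table.frame else None
    return xgb.DMatrix(X.to_numpy(float), label=y, feature_names=columns,
                       missing=np.nan)


def train(train_table: FeatureTable, val_table: FeatureTable,
          config: TrainConfig = TrainConfig(),
          window_end: str | None = None) -> SuppressionModel:
    """Fit the booster with validation-monitored early stopping."""
    if len(train_table) == 0 or len(val_table) == 0:
        raise ValueError("train and validation folds must be non-empty")
    y = train_table.y.to_numpy()
    if y.min() == y.max():
        raise ValueError("training fold contains a single class")
    columns = list(FEATURE_COLUMNS)
    dtrain = _dmatrix(train_table, columns)
    dval = _dmatrix(val_table, columns)
    history: dict = {}
    booster = xgb.train(
        config.xgb_params(), dtrain,
        num_boost_round=config.max_rounds,
        evals=[(dval, "validation")],
        early_stopping_rounds=config.early_stopping_rounds,
        evals_result=history,
        verbose_eval=False,
    )
    best = getattr(booster, "best_iteration", None)
    if best is None:
        best = config.max_rounds - 1
    return SuppressionModel(booster=booster, feature_columns=columns,
                            encoders=dict(train_table.encoders),
                            best_iteration=int(best), train_config=config,
                            window_end=window_end, eval_history=history)


def score(model: SuppressionModel, table: FeatureTable) -> np.ndarray:
    """Predicted interaction probabilities, one per row, in [0, 1]."""
    cols = [c for c in model.feature_columns
            if c not in table.frame.columns]
    if cols:
        raise ValueError(f"feature column(s) missing at scoring: {cols}")
    if len(table) == 0:
        return np.empty(0)
    dm = _dmatrix(table, model.feature_columns)
    return model.booster.predict(
        dm, iteration_range=(0, model.best_iteration + 1))


def cross_validate(table: FeatureTable, k: int = 5,
                   config: TrainConfig = TrainConfig(),
                   seed: int = 0) -> CvReport:
    """Clinician-level k-fold CV of AUROC / AUPRC.

    Each round holds one clinician fold out; the remaining clinicians are
    split 80/20 (again at clinician level) into a fit set and an
    early-stopping monitor.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    clinicians = np.array(sorted(table.frame["clinician_id"].unique()))
    if len(clinicians) < k:
        raise ValueError(f"need >= {k} clinicians, got {len(clinicians)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(clinicians)
    folds = np.array_split(perm, k)
    auroc, auprc = [], []
    for i, held in enumerate(folds):
        held = set(held)
        rest = [c for c in perm if c not in held]
        n_fit = max(1, int(round(0.8 * len(rest))))
        fit_ids, mon_ids = set(rest[:n_fit]), set(rest[n_fit:])

        def sub(ids: set) -> FeatureTable:
            m = table.frame["clinician_id"].isin(ids).to_numpy()
            return FeatureTable(table.frame.loc[m].reset_index(drop=True),
                                encoders=table.encoders, meta=table.meta)

        model = train(sub(fit_ids), sub(mon_ids),
                      config=TrainConfig(**{**asdict(config),
                                            "seed": config.seed + i}))
        test = sub(held)
        s = score(model, test)
        y = test.y.to_numpy()
        if y.min() == y.max():  # degenerate held-out fold
            continue
        auroc.append(float(roc_auc_score(y, s)))
        auprc.append(float(average_precision_score(y, s)))
    if not auroc:
        raise ValueError("no evaluable fold (all held-out folds one-class)")
    return CvReport(auroc=auroc, auprc=auprc)
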