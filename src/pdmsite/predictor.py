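"""Per-atom-type bagged neural predictors with calibration and thresholds.

One bagged ensemble of small feed-forward networks (54 inputs -> one hidden
layer -> sigmoid output) is trained for each protein atom type present in
the training corpus.  Raw ensemble outputs ("activities") are normalized to
confidence levels with a monotone calibration map estimated on a validation
set, which makes outputs of different atom-type models comparable; a
per-type decision threshold maximizing validation MCC gives binary atom
calls.  Cross-validation splits at the structure level (not the atom level)
so near-duplicate atoms of one protein can never straddle a split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.neural_network import MLPClassifier

from .features import attribute_columns
from .metrics import Confusion, confusion_metrics, mcc

__all__ = [
    "PredictorConfig",
    "BaggedModel",
    "CalibrationMap",
    "TypedPredictor",
    "ATTRIBUTE_SUBSETS",
    "train_bagged",
    "predict_activity",
    "calibrate",
    "optimize_threshold",
    "crossvalidate_10fold",
]

# named attribute subsets (0-based column indices into the 54-vector):
# P = interacting protein types, W = water, L = interacting ligand types,
# G = local geometry
ATTRIBUTE_SUBSETS: dict[str, list[int]] = {
    "PLWG": list(range(54)),
    "PLW": list(range(53)),
    "PWG": list(range(31)) + [53],
    "LWG": list(range(30, 54)),
    "LW": list(range(30, 53)),
    "LG": list(range(31, 54)),
    "L": list(range(31, 53)),
    "P": list(range(30)),
}


@dataclass(frozen=True)
class PredictorConfig:
    hidden_units: int = 10
    n_bags: int = 10
    max_iter: int = 200
    neg_pos_ratio: float = 5.0   # negative downsampling cap per bag
    min_examples: int = 20
    n_calibration_bins: int = 20
    threshold_grid: float = 0.01
    alpha: float = 1e-4          # L2 penalty of the networks


@dataclass
class BaggedModel:
    atom_type: int
    members: list
    seed: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a bagged model needs at least 2 members")


def _bootstrap_indices(y: np.ndarray, rng, neg_pos_ratio: float) -> np.ndarray:
    """Stratified bootstrap with negative downsampling to <= ratio : 1."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_neg = min(len(neg), int(np.ceil(neg_pos_ratio * len(pos)))) or len(neg)
    take_pos = rng.choice(pos, size=len(pos), replace=True)
    take_neg = rng.choice(neg, size=n_neg, replace=True)
    return np.concatenate([take_pos, take_neg])


def train_bagged(X: np.ndarray, y: np.ndarray, n_bags: int = 10, seed: int = 0,
                 atom_type: int = 0,
                 config: PredictorConfig = PredictorConfig()) -> BaggedModel:
    """Train one bagged ensemble on labeled attribute vectors.

    Each member is fit on a stratified bootstrap resample (negatives capped
    at ``neg_pos_ratio`` per positive).  Deterministic given ``seed``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(X) < config.min_examples:
        raise ValueError(f"need at least {config.min_examples} examples, got {len(X)}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, atom_type])
    members = []
    for b in range(n_bags):
        idx = _bootstrap_indices(y, rng, config.neg_pos_ratio)
        # a bootstrap may still collapse to one class at tiny n; resample
        for _ in range(10):
            if len(np.unique(y[idx])) == 2:
                break
            idx = _bootstrap_indices(y, rng, config.neg_pos_ratio)
        net = MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=config.alpha,
            max_iter=config.max_iter,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        net.fit(X[idx], y[idx])
        members.append(net)
    return BaggedModel(atom_type=atom_type, members=members, seed=seed)


def predict_activity(model: BaggedModel, X: np.ndarray) -> np.ndarray:
    """Mean member output in [0, 1] for one or more attribute vectors."""
    X = np.atleast_2d(np.asarray(X, float))
    n_features = model.members[0].n_features_in_
    if X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} attributes, got {X.shape[1]}")
    acts = np.zeros(len(X))
    for net in model.members:
        pos_col = int(np.flatnonzero(net.classes_ == 1)[0])
        acts += net.predict_proba(X)[:, pos_col]
    return acts / len(model.members)


class CalibrationMap:
    """Monotone map from raw activity to a confidence level in [0, 1].

    Built by splitting validation activities into equal-count bins,
    assigning each bin its positive precision, then isotonic smoothing.
    """

    def __init__(self, iso: IsotonicRegression | None):
        self._iso = iso  # None = identity (insufficient validation data)

    def __call__(self, activity) -> np.ndarray:
        a = np.clip(np.asarray(activity, float), 0.0, 1.0)
        if self._iso is None:
            return a
        return np.clip(self._iso.predict(np.atleast_1d(a)), 0.0, 1.0).reshape(a.shape)


def calibrate(activities: np.ndarray, labels: np.ndarray,
              n_bins: int = 20) -> CalibrationMap:
    """Fit a calibration map on validation activities and binary labels."""
    a = np.asarray(activities, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration requires both classes in the validation set")
    order = np.argsort(a, kind="stable")
    a, y = a[order], y[order]
    n_bins = max(2, min(n_bins, len(a) // 2))
    edges = np.array_split(np.arange(len(a)), n_bins)
    xs, ps = [], []
    for bin_idx in edges:
        if len(bin_idx) == 0:
            continue  # empty bins merge into neighbors implicitly
        xs.append(a[bin_idx].mean())
        ps.append(y[bin_idx].mean())
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                             out_of_bounds="clip")
    iso.fit(np.asarray(xs), np.asarray(ps))
    return CalibrationMap(iso)


def optimize_threshold(activities: np.ndarray, labels: np.ndarray,
                       grid_step: float = 0.01) -> float:
    """Activity threshold maximizing validation MCC (ties -> lower value)."""
    a = np.asarray(activities, float)
    y = np.asarray(labels, int)
    if len(a) == 0 or len(np.unique(y)) < 2:
        raise ValueError("degenerate validation set for threshold optimization")
    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    best_t, best_m = grid[0], -np.inf
    for t in grid:
        pred = a > t
        m = mcc(Confusion.from_labels(pred, y))
        if m > best_m + 1e-12:
            best_m, best_t = m, t
    return float(best_t)


class TypedPredictor:
    """Per-atom-type models + calibration + thresholds, applied to feature tables."""

    def __init__(self, config: PredictorConfig = PredictorConfig(),
                 feature_indices: list[int] | None = None):
        self.config = config
        self.feature_indices = list(feature_indices) if feature_indices is not None \
            else list(range(54))
        self.models: dict[int, BaggedModel] = {}
        self.calibration: dict[int, CalibrationMap] = {}
        self.thresholds: dict[int, float] = {}

    # feature tables are DataFrames with type_id, label and attribute columns
    def _xy(self, table: pd.DataFrame):
        cols = [attribute_columns()[i] for i in self.feature_indices]
        return table[cols].to_numpy(float), table["label"].to_numpy(int)

    def fit(self, train: pd.DataFrame, validation: pd.DataFrame, seed: int = 0) -> "TypedPredictor":
        per_type_val: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for atom_type, sub in train.groupby("type_id"):
            X, y = self._xy(sub)
            if len(X) < self.config.min_examples or len(np.unique(y)) < 2:
                continue  # too little data; atoms of this type score 0
            model = train_bagged(X, y, self.config.n_bags, seed,
                                 int(atom_type), self.config)
            self.models[int(atom_type)] = model
            val = validation[validation["type_id"] == atom_type]
            if len(val):
                Xv, yv = self._xy(val)
                per_type_val[int(atom_type)] = (predict_activity(model, Xv), yv)
        if not self.models:
            raise ValueError("no atom type had enough training data")
        # pooled validation activities back up types whose own validation
        # slice is degenerate: raw activities are not comparable across
        # models, so an uncalibrated identity map would break the leveled
        # ground the patch thresholds assume
        pooled_a = np.concatenate([a for a, _ in per_type_val.values()]) \
            if per_type_val else np.array([])
        pooled_y = np.concatenate([y for _, y in per_type_val.values()]) \
            if per_type_val else np.array([])
        pooled_ok = len(pooled_y) > 0 and len(np.unique(pooled_y)) == 2
        global_cal = calibrate(pooled_a, pooled_y, self.config.n_calibration_bins) \
            if pooled_ok else CalibrationMap(None)
        global_thr = optimize_threshold(pooled_a, pooled_y,
                                        self.config.threshold_grid) if pooled_ok else 0.5
        for atom_type in self.models:
            av, yv = per_type_val.get(atom_type, (np.array([]), np.array([])))
            if len(av) and len(np.unique(yv)) == 2:
                self.calibration[atom_type] = calibrate(
                    av, yv, self.config.n_calibration_bins)
                self.thresholds[atom_type] = optimize_threshold(
                    av, yv, self.config.threshold_grid)
            else:
                self.calibration[atom_type] = global_cal
                self.thresholds[atom_type] = global_thr
        return self

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Activities, confidences and positive calls for a feature table."""
        out = table.copy()
        activity = np.zeros(len(table))
        confidence = np.zeros(len(table))
        positive = np.zeros(len(table), bool)
        for atom_type, sub in table.groupby("type_id"):
            model = self.models.get(int(atom_type))
            if model is None:
                continue
            X = sub[[attribute_columns()[i] for i in self.feature_indices]].to_numpy(float)
            a = predict_activity(model, X)
            c = self.calibration[int(atom_type)](a)
            idx = sub.index
            activity[table.index.get_indexer(idx)] = a
            confidence[table.index.get_indexer(idx)] = c
            positive[table.index.get_indexer(idx)] = a > self.thresholds[int(atom_type)]
        out["activity"] = activity
        out["confidence"] = confidence
        out["positive"] = positive
        return out

    def save(self, path) -> None:
        import joblib

        joblib.dump({"config": self.config, "feature_indices": self.feature_indices,
                     "models": self.models, "calibration": self.calibration,
                     "thresholds": self.thresholds}, path)

    @classmethod
    def load(cls, path) -> "TypedPredictor":
        import joblib

        data = joblib.load(path)
        obj = cls(data["config"], data["feature_indices"])
        obj.models = data["models"]
        obj.calibration = data["calibration"]
        obj.thresholds = data["thresholds"]
        return obj


def fold_assignment(structure_ids: list, seed: int, n_folds: int = 10) -> dict:
    """Deterministic structure-level fold labels."""
    ids = sorted(set(structure_ids))
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} structures, got {len(ids)}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xF01D])
    perm = rng.permutation(len(ids))
    return {ids[p]: i % n_folds for i, p in enumerate(perm)}


def crossvalidate_10fold(examples: pd.DataFrame, seed: int = 0,
                         config: PredictorConfig = PredictorConfig(),
                         feature_indices: list[int] | None = None,
                         n_folds: int = 10) -> dict:
    """Structure-level 10-fold cross-validation of the typed predictors.

    Each fold uses 8/10 of the structures for training, 1/10 as the
    validation set (calibration + thresholds) and 1/10 as the test set.
    Returns per-fold confusions/metrics, the pooled confusion, and the
    per-atom test predictions of every fold.
    """
    folds = fold_assignment(examples["structure_id"].tolist(), seed, n_folds)
    fold_of = examples["structure_id"].map(folds)
    results = {"folds": [], "predictions": []}
    pooled = Confusion(0, 0, 0, 0)
    for k in range(n_folds):
        test_mask = fold_of == k
        val_mask = fold_of == (k + 1) % n_folds
        train_mask = ~(test_mask | val_mask)
        predictor = TypedPredictor(config, feature_indices).fit(
            examples[train_mask], examples[val_mask], seed=seed * n_folds + k)
        pred = predictor.predict(examples[test_mask])
        pred = pred.assign(fold=k)
        conf = Confusion.from_labels(pred["positive"], pred["label"])
        pooled = pooled + conf
        results["folds"].append({
            "fold": k,
            "test_structures": sorted(set(pred["structure_id"])),
            "confusion": conf,
            "metrics": confusion_metrics(conf),
        })
        results["predictions"].append(pred)
    results["predictions"] = pd.concat(results["predictions"], ignore_index=True)
    results["pooled_confusion"] = pooled
    results["pooled_metrics"] = confusion_metrics(pooled)
    results["mean_mcc"] = float(np.mean([f["metrics"]["MCC"] for f in results["folds"]]))
    return results
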