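"""Bagged predictors, calibration, threshold optimization and CV mechanics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neural_network import MLPClassifier

from pdmsite.features import attribute_columns
from pdmsite.metrics import Confusion, mcc
from pdmsite.predictor import (
    ATTRIBUTE_SUBSETS,
    BaggedModel,
    CalibrationMap,
    PredictorConfig,
    TypedPredictor,
    calibrate,
    crossvalidate_10fold,
    fold_assignment,
    optimize_threshold,
    predict_activity,
    train_bagged,
)

FAST = PredictorConfig(n_bags=3, max_iter=120)


def separable_data(n=200, seed=0, flip=0.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(0, 1, (n, 54))
    X[:, 0] += 3.0 * y  # one strongly informative attribute
    if flip:
        swap = rng.random(n) < flip
        y = np.where(swap, 1 - y, y)
    return X, y


def test_train_bagged_separable_high_mcc():
    X, y = separable_data(seed=1)
    model = train_bagged(X, y, n_bags=3, seed=0, atom_type=3, config=FAST)
    act = predict_activity(model, X)
    m = mcc(Confusion.from_labels(act > 0.5, y))
    assert m >= 0.9


def test_train_bagged_null_on_permuted_labels():
    mccs = []
    for seed in range(10):
        X, y = separable_data(n=150, seed=seed)
        rng = np.random.default_rng(seed + 100)
        y_perm = rng.permutation(y)
        Xtr, Xte = X[:100], X[100:]
        ytr, yte = y_perm[:100], y_perm[100:]
        model = train_bagged(Xtr, ytr, n_bags=3, seed=seed, config=FAST)
        act = predict_activity(model, Xte)
        mccs.append(mcc(Confusion.from_labels(act > 0.5, yte)))
    assert abs(np.mean(mccs)) < 0.15


def test_train_bagged_deterministic():
    X, y = separable_data(seed=2)
    a1 = predict_activity(train_bagged(X, y, 3, seed=7, config=FAST), X)
    a2 = predict_activity(train_bagged(X, y, 3, seed=7, config=FAST), X)
    assert np.array_equal(a1, a2)


def test_train_bagged_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(50, 54))
    with pytest.raises(ValueError, match="both classes"):
        train_bagged(X, np.zeros(50, int), 3, config=FAST)


def test_predict_activity_matches_manual_forward_pass():
    """One member, two hidden units, hand-set weights vs matrix arithmetic."""
    net = MLPClassifier(hidden_layer_sizes=(2,), activation="logistic",
                        max_iter=5)
    X0 = np.array([[0.0] * 54, [1.0] * 54])
    net.fit(X0, [0, 1])
    W1 = np.zeros((54, 2))
    W1[0, 0], W1[1, 1] = 1.0, -2.0
    b1 = np.array([0.5, -0.5])
    W2 = np.array([[1.5], [-1.0]])
    b2 = np.array([0.25])
    net.coefs_ = [W1, W2]
    net.intercepts_ = [b1, b2]
    model = BaggedModel(atom_type=1, members=[net, net], seed=0)
    v = np.zeros(54)
    v[0], v[1] = 0.8, 0.3
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    hidden = sig(v @ W1 + b1)
    expected = sig(hidden @ W2 + b2)[0]
    got = predict_activity(model, v)
    assert got[0] == pytest.approx(expected, abs=1e-9)


def test_predict_activity_checks_length():
    X, y = separable_data(seed=3)
    model = train_bagged(X, y, 3, config=FAST)
    with pytest.raises(ValueError, match="attributes"):
        predict_activity(model, np.zeros(10))
    a = predict_activity(model, np.vstack([X[0], X[0]]))
    assert a[0] == a[1]  # identical vectors, identical activity


def test_calibration_perfectly_ranked():
    act = np.linspace(0, 1, 200)
    labels = (act > 0.5).astype(int)
    cal = calibrate(act, labels)
    xs = np.linspace(0, 1, 50)
    ys = cal(xs)
    assert np.all(np.diff(ys) >= -1e-12)  # monotone
    assert cal(0.99) == pytest.approx(1.0)
    assert cal(0.01) == pytest.approx(0.0)


def test_calibration_random_is_flat_at_base_rate():
    rng = np.random.default_rng(4)
    act = rng.uniform(0, 1, 2000)
    labels = rng.random(2000) < 0.3
    cal = calibrate(act, labels.astype(int))
    ys = cal(np.linspace(0.05, 0.95, 10))
    assert np.all(np.abs(ys - 0.3) < 0.12)  # within binomial noise


def test_calibration_quality_rank_correlation():
    rng = np.random.default_rng(5)
    act = rng.uniform(0, 1, 3000)
    labels = (rng.random(3000) < act).astype(int)  # P(pos) = activity
    cal = calibrate(act, labels)
    bins = np.linspace(0, 1, 11)
    conf = np.asarray(cal(act))
    means = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (conf >= lo) & (conf < hi)
        if sel.sum() > 20:
            means.append((lo, labels[sel].mean()))
    from scipy.stats import spearmanr

    rho = spearmanr([m[0] for m in means], [m[1] for m in means]).statistic
    assert rho > 0.9


def test_calibration_requires_both_classes():
    with pytest.raises(ValueError):
        calibrate(np.linspace(0, 1, 50), np.zeros(50, int))


def test_threshold_constructed_optimum():
    rng = np.random.default_rng(6)
    act = rng.uniform(0, 1, 4000)
    labels = (act > 0.7).astype(int)
    t = optimize_threshold(act, labels)
    assert abs(t - 0.70) <= 0.01 + 1e-9


def test_threshold_tie_goes_low():
    act = np.array([0.99, 0.995, 0.97, 0.98])
    labels = np.array([1, 1, 0, 1])
    # below 0.97 every threshold gives identical confusion: lowest grid wins
    t = optimize_threshold(act, labels)
    assert t <= 0.97


def test_threshold_matches_exhaustive_search():
    rng = np.random.default_rng(8)
    act = rng.uniform(0, 1, 300)
    labels = (rng.random(300) < act ** 2).astype(int)
    t = optimize_threshold(act, labels)
    best = max(np.arange(0.01, 1.0, 0.01),
               key=lambda th: mcc(Confusion.from_labels(act > th, labels)))
    m_got = mcc(Confusion.from_labels(act > t, labels))
    m_best = mcc(Confusion.from_labels(act > best, labels))
    assert m_got == pytest.approx(m_best, abs=1e-12)


def _toy_examples(n_structures=12, atoms_per=40, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    cols = attribute_columns()
    for sid in range(n_structures):
        for _ in range(atoms_per):
            label = int(rng.random() < 0.3)
            v = rng.normal(0, 0.1, 54).clip(0, 1)
            v[0] = np.clip(0.5 * label + rng.normal(0, 0.15), 0, 1)
            t = int(rng.integers(1, 4))
            rows.append({"structure_id": f"S{sid:02d}", "atom_index": len(rows),
                         "type_id": t, "label": label,
                         **dict(zip(cols, v))})
    return pd.DataFrame(rows)


def test_fold_assignment_properties():
    ids = [f"S{i:02d}" for i in range(12)]
    folds = fold_assignment(ids, seed=3)
    assert set(folds.values()) <= set(range(10))
    assert fold_assignment(ids, seed=3) == folds  # deterministic
    counts = pd.Series(list(folds.values())).value_counts()
    assert counts.max() - counts.min() <= 1
    with pytest.raises(ValueError):
        fold_assignment(ids[:5], seed=0)


def test_crossvalidation_accounting_and_pooling():
    examples = _toy_examples()
    res = crossvalidate_10fold(examples, seed=1, config=FAST)
    seen = [sid for f in res["folds"] for sid in f["test_structures"]]
    assert sorted(seen) == sorted(examples["structure_id"].unique())
    pooled = res["pooled_confusion"]
    total = Confusion(0, 0, 0, 0)
    for f in res["folds"]:
        total = total + f["confusion"]
    assert (pooled.tp, pooled.tn, pooled.fp, pooled.fn) == \
        (total.tp, total.tn, total.fp, total.fn)
    # informative attribute -> positive pooled MCC
    assert res["pooled_metrics"]["MCC"] > 0.3
    res2 = crossvalidate_10fold(examples, seed=1, config=FAST)
    assert res2["mean_mcc"] == res["mean_mcc"]  # fixed seed reproducibility


def test_attribute_subsets_definition():
    assert ATTRIBUTE_SUBSETS["PLWG"] == list(range(54))
    assert ATTRIBUTE_SUBSETS["P"] == list(range(30))
    assert ATTRIBUTE_SUBSETS["L"] == list(range(31, 53))
    assert 30 in ATTRIBUTE_SUBSETS["LW"] and 53 not in ATTRIBUTE_SUBSETS["LW"]
    assert 53 in ATTRIBUTE_SUBSETS["LG"] and 30 not in ATTRIBUTE_SUBSETS["LG"]


def test_typed_predictor_round_trip(tmp_path):
    examples = _toy_examples()
    folds = fold_assignment(examples["structure_id"].tolist(), seed=0)
    val = examples["structure_id"].map(folds) == 0
    pred = TypedPredictor(FAST).fit(examples[~val], examples[val], seed=0)
    out = pred.predict(examples[val])
    assert {"activity", "confidence", "positive"} <= set(out.columns)
    assert out["confidence"].between(0, 1).all()
    path = tmp_path / "models.joblib"
    pred.save(path)
    again = TypedPredictor.load(path)
    out2 = again.predict(examples[val])
    assert np.array_equal(out["confidence"].to_numpy(), out2["confidence"].to_numpy())
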