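"""SVM decoding, recursive feature elimination, transfer/within protocols."""

import numpy as np
import pytest
from scipy import stats as sp_stats
from sklearn.model_selection import StratifiedKFold

from conftest import make_epochs

from attndecode.csp import FeatureMatrix
from attndecode.decode import (DecodingConfig, decode_transfer, decode_within,
                               encode_labels, eog_features, hinge_loss, rfe_cv,
                               split_by_condition, standardize_features,
                               train_linear_svm)
from attndecode.preprocess import preprocess_session
from attndecode.synth import SessionConfig, generate_session


def null_interval_99(n):
    return (sp_stats.binom.ppf(0.005, n, 0.5) / n,
            sp_stats.binom.ppf(0.995, n, 0.5) / n)


# --------------------------------------------------------------------------
# feature plumbing


def test_standardization_example_and_train_statistics():
    train = FeatureMatrix(np.array([[0.0], [4.0]]), ["f0"], "csp")  # mean 2, sd 2
    test = FeatureMatrix(np.array([[4.0]]), ["f0"], "csp")
    tr, te = standardize_features(train, test)
    assert te.values[0, 0] == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    train = FeatureMatrix(rng.normal(3, 2, size=(50, 4)),
                          [f"f{i}" for i in range(4)], "csp")
    tr, _ = standardize_features(train)
    assert np.allclose(tr.values.mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(tr.values.var(axis=0), 1.0, atol=1e-8)


def test_standardization_uses_no_test_statistics():
    rng = np.random.default_rng(1)
    train = FeatureMatrix(rng.normal(size=(30, 3)), ["a", "b", "c"], "csp")
    test = FeatureMatrix(rng.normal(size=(10, 3)), ["a", "b", "c"], "csp")
    shifted = FeatureMatrix(test.values + 5.0, test.feature_names, "csp")
    _, te = standardize_features(train, test)
    _, te_shift = standardize_features(train, shifted)
    sd = train.values.std(axis=0)
    assert np.allclose(te_shift.values, te.values + 5.0 / sd, atol=1e-10)


def test_zero_variance_feature_dropped_with_warning(caplog):
    vals = np.column_stack([np.ones(10), np.arange(10.0)])
    train = FeatureMatrix(vals, ["const", "ramp"], "csp")
    with caplog.at_level("WARNING"):
        tr, _ = standardize_features(train)
    assert tr.feature_names == ["ramp"]
    assert "const" in caplog.text


def test_eog_features_are_epoch_means():
    T = 128
    heog = np.full(T, -3.0)
    veog = np.full(T, 5.0)
    ep = make_epochs(np.zeros((1, 2, T)), eog=np.stack([[heog, veog]]))
    fm = eog_features(ep)
    assert fm.values[0].tolist() == [-3.0, 5.0]
    # zero-mean sinusoid over the epoch averages out
    t = np.arange(T)
    sine = np.sin(2 * np.pi * 4 * t / T)
    ep2 = make_epochs(np.zeros((1, 2, T)), eog=np.stack([[sine, sine]]))
    assert np.allclose(eog_features(ep2).values, 0.0, atol=1e-12)
    rng = np.random.default_rng(2)
    eog = rng.standard_normal((3, 2, T))
    fm3 = eog_features(make_epochs(np.zeros((3, 2, T)), eog=eog))
    assert np.allclose(fm3.values, eog.mean(axis=2), atol=1e-12)


# --------------------------------------------------------------------------
# linear SVM


def test_separable_problem_reaches_perfect_training_accuracy():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(-5, 0.3, size=(40, 2)),
                   rng.normal(5, 0.3, size=(40, 2))])
    y = np.r_[np.full(40, -1), np.full(40, 1)]
    model = train_linear_svm(X, y, c=10.0, max_iter=5000)
    assert model.score(X, y) == 1.0
    assert hinge_loss(model, X, y) < 0.1


def test_one_class_and_invalid_c_rejected():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        train_linear_svm(X, np.ones(5), c=1.0)
    with pytest.raises(ValueError):
        train_linear_svm(X, np.r_[np.ones(3), -np.ones(2)], c=0.0)


def test_informative_feature_receives_largest_weight():
    rng = np.random.default_rng(4)
    n = 300
    y = np.where(rng.random(n) < 0.5, -1, 1)
    X = rng.standard_normal((n, 5))
    X[:, 2] += 2.0 * y
    model = train_linear_svm(X, y, c=1.0)
    assert np.argmax(np.abs(model.coef_.ravel())) == 2


def test_uninformative_features_decode_at_chance():
    rng = np.random.default_rng(5)
    n = 1000
    X = rng.standard_normal((n, 5))
    y = np.where(rng.random(n) < 0.5, -1, 1)
    correct = 0
    for tr, te in StratifiedKFold(10, shuffle=True, random_state=0).split(X, y):
        model = train_linear_svm(X[tr], y[tr], c=1.0)
        correct += int(np.sum(model.predict(X[te]) == y[te]))
    lo, hi = null_interval_99(n)
    assert lo <= correct / n <= hi


# --------------------------------------------------------------------------
# recursive feature elimination


def test_rfe_recovers_planted_informative_feature():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 400
        y = np.where(rng.random(n) < 0.5, -1, 1)
        X = rng.standard_normal((n, 16))
        X[:, 7] += 2.0 * y
        config = DecodingConfig(c_grid=[0.1, 1.0, 10.0], seed=seed)
        sel = rfe_cv(X, y, config)
        hits += 7 in sel.selected_features
    assert hits >= 9


def test_rfe_on_pure_noise_terminates_with_nonempty_set():
    rng = np.random.default_rng(6)
    n = 80
    X = rng.standard_normal((n, 8))
    y = np.where(rng.random(n) < 0.5, -1, 1)
    config = DecodingConfig(c_grid=[0.1, 1.0], seed=0)
    sel = rfe_cv(X, y, config)
    assert len(sel.selected_features) >= 1
    assert sel.chosen_c in (0.1, 1.0)


def test_rfe_matches_independent_reimplementation():
    rng = np.random.default_rng(7)
    n = 20
    y = np.r_[np.full(10, -1), np.full(10, 1)]
    X = rng.standard_normal((n, 4))
    X[:, 1] += 1.5 * y
    c_grid = [0.5, 2.0]
    config = DecodingConfig(c_grid=c_grid, seed=9)
    sel = rfe_cv(X, y, config)

    # independent, straightforward re-implementation of the same greedy loop
    def scale(a, b):
        m, s = a.mean(0), a.std(0)
        s = np.where(s > 0, s, 1.0)
        return (a - m) / s, None if b is None else (b - m) / s

    sizes = [4, 3, 2, 1]
    loss = np.zeros((10, len(sizes), len(c_grid)))
    skf = StratifiedKFold(10, shuffle=True, random_state=9)
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = scale(X[tr], X[te])
        for ci, c in enumerate(c_grid):
            active = [0, 1, 2, 3]
            model = train_linear_svm(Xtr[:, active], y[tr], c, seed=9)
            for si, size in enumerate(sizes):
                while len(active) > size:
                    w2 = model.coef_.ravel() ** 2
                    active.pop(int(np.argsort(w2, kind="stable")[0]))
                    model = train_linear_svm(Xtr[:, active], y[tr], c, seed=9)
                loss[fi, si, ci] = hinge_loss(model, Xte[:, active], y[te])
    mean_loss = loss.mean(axis=0)
    assert np.allclose(sel.mean_loss, mean_loss, atol=1e-12)
    best = mean_loss.min()
    cands = sorted((sizes[si], c_grid[ci])
                   for si, ci in np.argwhere(mean_loss == best))
    assert (sel.chosen_size, sel.chosen_c) == cands[0]
    # final identities from refitting the elimination on all trials
    Xall, _ = scale(X, None)
    active = [0, 1, 2, 3]
    model = train_linear_svm(Xall, y, sel.chosen_c, seed=9)
    while len(active) > sel.chosen_size:
        w2 = model.coef_.ravel() ** 2
        active.pop(int(np.argsort(w2, kind="stable")[0]))
        model = train_linear_svm(Xall[:, active], y, sel.chosen_c, seed=9)
    assert sel.selected_features == tuple(sorted(active))


def test_rfe_requires_enough_trials_and_features():
    with pytest.raises(ValueError):
        rfe_cv(np.zeros((8, 0)), np.r_[np.ones(4), -np.ones(4)],
               DecodingConfig(c_grid=[1.0]))
    with pytest.raises(ValueError):
        rfe_cv(np.zeros((8, 3)), np.r_[np.ones(4), -np.ones(4)],
               DecodingConfig(c_grid=[1.0], n_folds=10))


def test_decoding_config_default_grid_contract():
    config = DecodingConfig()
    assert len(config.c_grid) == 100
    assert config.c_grid[0] == pytest.approx(1e-5)
    assert config.c_grid[-1] == pytest.approx(1e5)
    assert np.all(np.diff(config.c_grid) > 0)
    assert config.n_folds == 10
    assert config.elimination_step == 1
    with pytest.raises(ValueError):
        DecodingConfig(c_grid=[1.0, 0.5])


# --------------------------------------------------------------------------
# transfer and within-condition protocols


@pytest.fixture(scope="module")
def strong_split(decode_epochs):
    return split_by_condition(decode_epochs)


def test_transfer_decodes_planted_signal(strong_split):
    pred, amb = strong_split
    res = decode_transfer(pred, amb, DecodingConfig.fast(seed=0))
    assert res.p_value < 0.05
    assert res.accuracy == res.k_correct / res.n_trials
    assert res.n_trials == amb.n_trials
    assert len(res.selected_features) >= 1


def test_transfer_and_within_results_are_deterministic(strong_split):
    pred, amb = strong_split
    config = DecodingConfig.fast(seed=4)
    a = decode_transfer(pred, amb, config)
    b = decode_transfer(pred, amb, config)
    assert a.to_dict() == b.to_dict()
    assert np.array_equal(a.predictions, b.predictions)


def test_within_decoding_reports_folds_and_beats_chance(strong_split):
    pred, _ = strong_split
    res = decode_within(pred, DecodingConfig.fast(seed=1))
    assert len(res.per_fold_accuracies) == 10
    assert res.p_value < 0.05
    assert res.accuracy == pytest.approx(res.k_correct / res.n_trials)


def test_shuffled_labels_stay_at_chance_but_leaky_csp_inflates(strong_split):
    pred, _ = strong_split
    shuffled = pred.subset(np.arange(pred.n_trials))
    rng = np.random.default_rng(0)
    shuffled.labels = rng.permutation(np.asarray(pred.labels))
    config = DecodingConfig.fast(seed=2)
    fair = decode_within(shuffled, config)
    lo, hi = null_interval_99(fair.n_trials)
    assert lo <= fair.accuracy <= hi
    # fitting CSP once on all trials (test folds included) leaks class
    # structure into the filters and inflates shuffled-label accuracy
    leaky = decode_within(shuffled, config, refit_csp_per_fold=False)
    assert leaky.accuracy > fair.accuracy
    assert leaky.accuracy > hi


def test_noiseless_planted_separation_is_perfect():
    cfg = SessionConfig(n_blocks=2, trials_per_block=26, sfreq=256.0,
                        noise_amplitude=1e-3, modulation_depth=2.0,
                        amplitude_jitter=0.05, artifact_fraction=0.0)
    epochs = preprocess_session(generate_session(cfg, seed=8))
    pred, amb = split_by_condition(epochs)
    res = decode_transfer(pred, amb, DecodingConfig(c_grid=[0.1, 1.0, 10.0],
                                                    elimination_step=8, seed=0))
    assert res.accuracy == 1.0


def test_eog_features_carry_no_class_information(strong_split):
    pred, amb = strong_split
    res = decode_transfer(pred, amb, DecodingConfig.fast(seed=3),
                          feature_kind="eog")
    lo, hi = null_interval_99(res.n_trials)
    assert lo <= res.accuracy <= hi


def test_accuracy_nondecreasing_in_modulation_depth():
    # scaled-down version of the monotonicity property: 3 seeds per depth
    means = []
    for depth in (0.0, 0.5, 1.0, 2.0):
        accs = []
        for seed in (41, 42, 43):
            cfg = SessionConfig(n_blocks=3, trials_per_block=40, sfreq=256.0,
                                modulation_depth=depth, artifact_fraction=0.0)
            epochs = preprocess_session(generate_session(cfg, seed))
            pred, _ = split_by_condition(epochs)
            res = decode_within(pred, DecodingConfig(
                c_grid=[0.1, 1.0, 10.0], elimination_step=8, seed=seed))
            accs.append(res.accuracy)
        means.append(np.mean(accs))
    inversions = sum(b < a - 1e-12 for a, b in zip(means, means[1:]))
    assert inversions <= 1


def test_transfer_validates_inputs(strong_split):
    pred, amb = strong_split
    empty = pred.subset(np.array([], dtype=int))
    with pytest.raises(ValueError):
        decode_transfer(empty, amb, DecodingConfig.fast())
    unlabeled = pred.subset(np.arange(pred.n_trials))
    unlabeled.labels = None
    with pytest.raises(ValueError):
        decode_transfer(unlabeled, amb, DecodingConfig.fast())
    with pytest.raises(ValueError):
        encode_labels(["left", "up"])
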