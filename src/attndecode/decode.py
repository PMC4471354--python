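"""Linear SVM decoding with recursive feature elimination and cross-validation.

The selection protocol follows the transfer design: feature sets and the
regularization parameter C are chosen on predictive-cue trials by
recursive feature elimination evaluated with the unregularized mean
hinge loss over stratified 10-fold cross-validation, jointly over a
log-spaced C grid. The final model is trained on all predictive trials
and either tested on ambiguous trials (transfer) or evaluated by an
outer cross-validation within the predictive condition, refitting the
CSP bank inside every outer training split so no test-set statistic
leaks into filters, scaling, or selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import stats
from .csp import FeatureMatrix, apply_csp, class_covariances, fit_csp
from .preprocess import EpochSet
from .synth import AMBIGUOUS, LEFT, PREDICTIVE, RIGHT

logger = logging.getLogger(__name__)

#: binary label encoding used throughout outputs
LABEL_CODE = {LEFT: -1, RIGHT: +1}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}


def _default_c_grid() -> np.ndarray:
    return np.logspace(-5, 5, 100)


@dataclass
class DecodingConfig:
    """Decoder hyper-parameters.

    The default C grid is 100 values log-spaced from 1e-5 to 1e5 with an
    elimination step of one feature per iteration. ``fast()`` returns the
    reduced profile used for full-session analyses (5-value grid over
    1e-2..1e2, step 4), which trades selection resolution for runtime.
    """

    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    n_folds: int = 10
    elimination_step: int = 1
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-3

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        if self.c_grid.ndim != 1 or len(self.c_grid) < 1:
            raise ValueError("c_grid must be a 1-D array")
        if np.any(self.c_grid <= 0) or np.any(np.diff(self.c_grid) <= 0):
            raise ValueError("c_grid must be positive and strictly increasing")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.elimination_step < 1:
            raise ValueError("elimination_step must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0) -> "DecodingConfig":
        return cls(c_grid=np.logspace(-2, 2, 5), elimination_step=4, seed=seed)


@dataclass
class DecodingResult:
    accuracy: float
    per_fold_accuracies: list[float] | None
    selected_features: tuple[int, ...]
    chosen_c: float
    predictions: np.ndarray           # "left" | "right" per test trial
    k_correct: int
    n_trials: int
    p_value: float
    mode: str = ""
    label_encoding: dict = field(default_factory=lambda: dict(LABEL_CODE))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_fold_accuracies": self.per_fold_accuracies,
            "selected_features": list(self.selected_features),
            "chosen_c": self.chosen_c,
            "k_correct": self.k_correct,
            "n_trials": self.n_trials,
            "p_value": self.p_value,
            "mode": self.mode,
            "label_encoding": {k: int(v) for k, v in self.label_encoding.items()},
        }


def encode_labels(labels) -> np.ndarray:
    """Map left/right labels to -1/+1."""
    try:
        return np.array([LABEL_CODE[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc


def standardize_features(train: FeatureMatrix,
                         test: FeatureMatrix | None = None,
                         ) -> tuple[FeatureMatrix, FeatureMatrix | None]:
    """Center and scale with training-set statistics only.

    Zero-variance training features are dropped (with a logged warning)
    from both sets. CSP and EOG feature matrices are separate objects, so
    the two blocks are standardized independently by construction.
    """
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping zero-variance feature(s) %s",
                       [train.feature_names[i] for i in np.flatnonzero(~keep)])
    mean, sd = mean[keep], sd[keep]
    names = [n for n, k in zip(train.feature_names, keep) if k]
    tr = FeatureMatrix((train.values[:, keep] - mean) / sd, names, train.kind,
                       standardization=(mean, sd))
    te = None
    if test is not None:
        te = FeatureMatrix((test.values[:, keep] - mean) / sd, names, test.kind,
                           standardization=(mean, sd))
    return tr, te


def eog_features(epochs: EpochSet) -> FeatureMatrix:
    """Average EOG signal value per epoch and channel (2 features/trial)."""
    if epochs.eog.size == 0 and epochs.n_trials > 0:
        raise ValueError("EOG tensor required")
    values = epochs.eog.astype(np.float64).mean(axis=2)
    return FeatureMatrix(values=values, feature_names=["hEOG", "vEOG"], kind="eog")


def train_linear_svm(features: np.ndarray, labels: np.ndarray, c: float,
                     seed: int = 0, max_iter: int = 300,
                     tol: float = 1e-3) -> LinearSVC:
    """L2-regularized hinge-loss linear classifier (liblinear dual).

    Iterations are capped: at extreme C the dual solver converges slowly
    and the capped weights are numerically indistinguishable for
    selection purposes. Deterministic given (features, labels, c, seed).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if c <= 0:
        raise ValueError("C must be positive")
    model = LinearSVC(C=c, loss="hinge", dual=True, random_state=seed,
                      max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(features, labels)
    return model


def hinge_loss(model: LinearSVC, features: np.ndarray,
               labels: np.ndarray) -> float:
    """Unregularized mean hinge loss max(0, 1 - y f(x)) on a test set."""
    margin = np.asarray(labels) * model.decision_function(features)
    return float(np.mean(np.maximum(0.0, 1.0 - margin)))


def _scale(train: np.ndarray, test: np.ndarray | None):
    """Per-feature train-stat scaling; constant features are centered only."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    tr = (train - mean) / sd
    te = None if test is None else (test - mean) / sd
    return tr, te


def _elimination_sizes(n_features: int, step: int) -> list[int]:
    sizes = [n_features]
    while sizes[-1] > 1:
        sizes.append(max(sizes[-1] - step, 1))
    return sizes


def _rfe_path(X_tr, y_tr, X_te, y_te, c, sizes, seed, max_iter, tol, step=1):
    """Greedy backward elimination over the visited ``sizes`` (descending).

    Each fitted model ranks the active features by squared weight; the
    ``step`` weakest are pruned per iteration and the model refitted.
    Returns the test-fold hinge loss and the active set at every size.
    """
    active = list(range(X_tr.shape[1]))
    losses = {}
    paths = {}
    model = train_linear_svm(X_tr[:, active], y_tr, c, seed=seed,
                             max_iter=max_iter, tol=tol)
    for size in sizes:
        while len(active) > size:
            w2 = model.coef_.ravel() ** 2
            k = min(step, len(active) - size)
            weakest = np.argsort(w2, kind="stable")[:k]
            for pos in sorted(map(int, weakest), reverse=True):
                active.pop(pos)
            model = train_linear_svm(X_tr[:, active], y_tr, c, seed=seed,
                                     max_iter=max_iter, tol=tol)
        if X_te is not None:
            losses[size] = hinge_loss(model, X_te[:, active], y_te)
        paths[size] = tuple(active)
    return losses, paths


@dataclass
class RFESelection:
    selected_features: tuple[int, ...]
    chosen_c: float
    chosen_size: int
    sizes: list[int]
    mean_loss: np.ndarray             # (n_sizes, n_c), ordered like sizes/c_grid
    fold_loss: np.ndarray             # (n_folds, n_sizes, n_c)


def rfe_cv(features, labels: np.ndarray, config: DecodingConfig) -> RFESelection:
    """Joint selection of feature-set size and C by cross-validated hinge loss.

    For every stratified fold and every C, features are recursively
    pruned by squared-weight ranking while the test-fold hinge loss is
    recorded at each visited size; the (size, C) pair minimizing the mean
    loss wins, with ties resolved toward fewer features, then smaller C.
    The reported feature identities come from re-running the elimination
    on all trials at the chosen (size, C).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels)
    if X.shape[1] < 1:
        raise ValueError("at least one feature required")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < config.n_folds:
        raise ValueError("need two classes with >= n_folds trials each")
    sizes = _elimination_sizes(X.shape[1], config.elimination_step)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    fold_loss = np.empty((config.n_folds, len(sizes), len(config.c_grid)))
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, X_te = _scale(X[tr], X[te])
        for ci, c in enumerate(config.c_grid):
            losses, _ = _rfe_path(X_tr, y[tr], X_te, y[te], c, sizes,
                                  config.seed, config.max_iter, config.tol,
                                  step=config.elimination_step)
            fold_loss[fi, :, ci] = [losses[s] for s in sizes]
    mean_loss = fold_loss.mean(axis=0)
    best = np.min(mean_loss)
    cand = np.argwhere(mean_loss == best)
    # ties: fewer features first (sizes is descending), then smaller C
    order = sorted(map(tuple, cand), key=lambda sc: (sizes[sc[0]], config.c_grid[sc[1]]))
    si, ci = order[0]
    chosen_size, chosen_c = sizes[si], float(config.c_grid[ci])
    X_all, _ = _scale(X, None)
    _, paths = _rfe_path(X_all, y, None, None, chosen_c, sizes,
                         config.seed, config.max_iter, config.tol,
                         step=config.elimination_step)
    selected = tuple(sorted(paths[chosen_size]))
    return RFESelection(selected_features=selected, chosen_c=chosen_c,
                        chosen_size=chosen_size, sizes=sizes,
                        mean_loss=mean_loss, fold_loss=fold_loss)


def _features_for(epochs: EpochSet, feature_kind: str, bank=None) -> FeatureMatrix:
    if feature_kind == "csp":
        return apply_csp(bank, epochs)
    if feature_kind == "eog":
        return eog_features(epochs)
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def decode_transfer(predictive: EpochSet, ambiguous: EpochSet,
                    config: DecodingConfig,
                    feature_kind: str = "csp") -> DecodingResult:
    """Train on predictive trials, decode ambiguous trials.

    The CSP bank, the feature selection, the regularization parameter,
    and the standardization statistics all derive from predictive trials
    only; no ambiguous statistic is used anywhere upstream of the test.
    """
    if predictive.n_trials == 0 or ambiguous.n_trials == 0:
        raise ValueError("both trial sets must be nonempty")
    if predictive.labels is None or ambiguous.labels is None:
        raise ValueError("both trial sets must be labeled")
    y_tr = encode_labels(predictive.labels)
    y_te = encode_labels(ambiguous.labels)
    bank = None
    if feature_kind == "csp":
        cov_l, cov_r = class_covariances(predictive)
        bank = fit_csp(cov_l, cov_r)
    f_tr = _features_for(predictive, feature_kind, bank)
    f_te = _features_for(ambiguous, feature_kind, bank)
    if f_tr.n_features != f_te.n_features:
        raise ValueError("train/test feature dimensions differ")
    sel = rfe_cv(f_tr.values, y_tr, config)
    X_tr, X_te = _scale(f_tr.values, f_te.values)
    idx = list(sel.selected_features)
    model = train_linear_svm(X_tr[:, idx], y_tr, sel.chosen_c,
                             seed=config.seed, max_iter=config.max_iter,
                             tol=config.tol)
    pred = model.predict(X_te[:, idx])
    k = int(np.sum(pred == y_te))
    n = len(y_te)
    p = stats.binomial_significance(k, n).p_value
    return DecodingResult(
        accuracy=k / n, per_fold_accuracies=None,
        selected_features=sel.selected_features, chosen_c=sel.chosen_c,
        predictions=np.array([CODE_LABEL[v] for v in pred], dtype=object),
        k_correct=k, n_trials=n, p_value=p, mode=f"transfer-{feature_kind}")


def decode_within(predictive: EpochSet, config: DecodingConfig,
                  feature_kind: str = "csp",
                  refit_csp_per_fold: bool = True) -> DecodingResult:
    """Outer stratified 10-fold CV within the predictive condition.

    Inside every outer training split the CSP bank is refitted and the
    inner RFE/CV selection re-run, so the outer test fold contributes to
    no statistic it is evaluated with. ``refit_csp_per_fold=False`` fits
    the bank once on all trials — a deliberately leaky diagnostic path
    used to demonstrate the inflation such leakage produces.
    """
    if predictive.labels is None:
        raise ValueError("trials must be labeled")
    y = encode_labels(predictive.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < config.n_folds:
        raise ValueError("need >= n_folds trials per class")
    bank_all = None
    if feature_kind == "csp" and not refit_csp_per_fold:
        bank_all = fit_csp(*class_covariances(predictive))
    outer = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                            random_state=config.seed + 10007)
    predictions = np.empty(len(y), dtype=int)
    fold_acc: list[float] = []
    fold_sel: list[tuple[int, ...]] = []
    fold_c: list[float] = []
    for tr, te in outer.split(predictive.data[:, 0, 0][:, None], y):
        ep_tr = predictive.subset(tr)
        ep_te = predictive.subset(te)
        bank = bank_all
        if feature_kind == "csp" and refit_csp_per_fold:
            ep_tr.labels = np.asarray(predictive.labels)[tr]
            bank = fit_csp(*class_covariances(ep_tr))
        f_tr = _features_for(ep_tr, feature_kind, bank)
        f_te = _features_for(ep_te, feature_kind, bank)
        sel = rfe_cv(f_tr.values, y[tr], config)
        X_tr, X_te = _scale(f_tr.values, f_te.values)
        idx = list(sel.selected_features)
        model = train_linear_svm(X_tr[:, idx], y[tr], sel.chosen_c,
                                 seed=config.seed, max_iter=config.max_iter,
                                 tol=config.tol)
        pred = model.predict(X_te[:, idx])
        predictions[te] = pred
        fold_acc.append(float(np.mean(pred == y[te])))
        fold_sel.append(sel.selected_features)
        fold_c.append(sel.chosen_c)
    k = int(np.sum(predictions == y))
    n = len(y)
    p = stats.binomial_significance(k, n).p_value
    union = tuple(sorted(set().union(*fold_sel)))
    cs, cnt = np.unique(fold_c, return_counts=True)
    chosen_c = float(cs[np.argmax(cnt)])  # modal fold choice, smallest on ties
    return DecodingResult(
        accuracy=k / n, per_fold_accuracies=fold_acc,
        selected_features=union, chosen_c=chosen_c,
        predictions=np.array([CODE_LABEL[v] for v in predictions], dtype=object),
        k_correct=k, n_trials=n, p_value=p, mode=f"within-{feature_kind}")


def split_by_condition(epochs: EpochSet) -> tuple[EpochSet, EpochSet]:
    """(predictive, ambiguous) subsets from the trial metadata."""
    cond = epochs.trial_meta["condition"].to_numpy()
    pred = epochs.subset(cond == PREDICTIVE)
    amb = epochs.subset(cond == AMBIGUOUS)
    pred.labels = None if epochs.labels is None else epochs.labels[cond == PREDICTIVE]
    amb.labels = None if epochs.labels is None else epochs.labels[cond == AMBIGUOUS]
    return pred, amb
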