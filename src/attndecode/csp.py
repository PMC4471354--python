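"""Regularized common spatial patterns.

Per-trial covariances are shrunk toward a scaled identity with the
oracle-approximating-shrinkage (OAS) closed-form intensity, averaged per
class, and the spatial filters W solve the generalized eigenvalue
problem Sigma_r W = lambda Sigma_l W. Columns are scaled so that
w' Sigma_l w = 1, making each eigenvalue the right-class variance of its
filtered signal; the patterns A = (W')^{-1} = Sigma_l W give the sensor
topographies of the underlying sources. Features are log10 variances of
the spatially filtered epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg

from .preprocess import EpochSet
from .synth import LEFT, RIGHT

#: eigenvalues closer than this are treated as tied and re-ordered
#: deterministically by the channel index of the largest pattern coefficient
EIGENVALUE_TIE_TOL = 1e-10


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    shrinkage_intensity: float
    class_label: str                 # "left" | "right" | "pooled"
    n_trials: int


@dataclass
class SpatialFilterBank:
    """CSP solution: filters W (columns), patterns A, descending eigenvalues.

    class_convention records the pencil orientation: the largest
    eigenvalue maximizes the right/left variance ratio, so the first
    filter is the most discriminative for right-attention trials and the
    last one for left-attention trials.
    """

    filters: np.ndarray              # W, (N, N)
    patterns: np.ndarray             # A = (W')^{-1}, (N, N)
    eigenvalues: np.ndarray          # descending
    class_convention: str = "lambda maximizes right/left variance ratio"

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


@dataclass
class FeatureMatrix:
    """Trials x features table of log-variance (or EOG-mean) values."""

    values: np.ndarray
    feature_names: list[str]
    kind: str                        # "csp" | "eog"
    standardization: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def oas_intensity(S: np.ndarray, n_samples: int) -> float:
    """Closed-form OAS shrinkage intensity toward (tr(S)/N) I.

    rho = min(1, [(1 - 2/N) tr(S^2) + tr(S)^2] /
                 [(n + 1 - 2/N) (tr(S^2) - tr(S)^2 / N)])
    """
    N = S.shape[0]
    tr = float(np.trace(S))
    tr2 = float(np.sum(S * S))       # tr(S @ S) for symmetric S
    denom = (n_samples + 1.0 - 2.0 / N) * (tr2 - tr ** 2 / N)
    if denom <= 0:
        return 1.0
    num = (1.0 - 2.0 / N) * tr2 + tr ** 2
    return float(min(1.0, num / denom))


def shrinkage_covariance(epoch: np.ndarray, shrinkage: float | None = None,
                         class_label: str = "pooled") -> CovarianceEstimate:
    """OAS-shrunk sample covariance of one epoch (channels x samples).

    The sample covariance S is taken over time samples after per-channel
    mean removal (divisor n). ``shrinkage`` overrides the automatic
    intensity (0 = no shrinkage, 1 = full shrinkage to (tr(S)/N) I).
    """
    X = np.asarray(epoch, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("epoch must be channels x samples with > 1 sample")
    if not np.any(X):
        raise ValueError("all-zero epoch has no covariance structure")
    Xc = X - X.mean(axis=1, keepdims=True)
    S = Xc @ Xc.T / X.shape[1]
    rho = oas_intensity(S, X.shape[1]) if shrinkage is None else float(shrinkage)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    mu = np.trace(S) / S.shape[0]
    mat = (1.0 - rho) * S + rho * mu * np.eye(S.shape[0])
    return CovarianceEstimate(matrix=mat, shrinkage_intensity=rho,
                              class_label=class_label, n_trials=1)


def trial_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (raw, OAS-shrunk) covariances, cached on the EpochSet.

    The raw covariances also back the log-variance features: the
    variance of a filtered signal w'X equals w' S w for the mean-removed
    sample covariance S.
    """
    if epochs._cov_raw is None:
        X = epochs.data.astype(np.float64)
        Xc = X - X.mean(axis=2, keepdims=True)
        T = X.shape[2]
        raw = np.einsum("tcs,tds->tcd", Xc, Xc, optimize=True) / T
        N = raw.shape[1]
        tr = np.trace(raw, axis1=1, axis2=2)
        tr2 = np.sum(raw * raw, axis=(1, 2))
        num = (1.0 - 2.0 / N) * tr2 + tr ** 2
        denom = (T + 1.0 - 2.0 / N) * (tr2 - tr ** 2 / N)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, np.minimum(1.0, num / denom), 1.0)
        mu = tr / N
        eye = np.eye(N)
        shrunk = ((1.0 - rho)[:, None, None] * raw
                  + (rho * mu)[:, None, None] * eye)
        epochs._cov_raw = raw
        epochs._cov_shrunk = shrunk
        epochs._shrinkage = rho
    return epochs._cov_raw, epochs._cov_shrunk


def class_covariances(epochs: EpochSet) -> tuple[CovarianceEstimate, CovarianceEstimate]:
    """Average per-trial shrinkage covariances for left and right trials."""
    if epochs.labels is None:
        raise ValueError("epochs must be labeled")
    _, shrunk = trial_covariances(epochs)
    out = []
    for label in (LEFT, RIGHT):
        mask = epochs.labels == label
        if mask.sum() < 2:
            raise ValueError(f"need >= 2 trials for class {label!r}")
        out.append(CovarianceEstimate(
            matrix=shrunk[mask].mean(axis=0),
            shrinkage_intensity=float(epochs._shrinkage[mask].mean()),
            class_label=label, n_trials=int(mask.sum())))
    return out[0], out[1]


def _as_matrix(cov) -> np.ndarray:
    return cov.matrix if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)


def fit_csp(cov_left, cov_right) -> SpatialFilterBank:
    """Solve Sigma_r W = lambda Sigma_l W via Cholesky whitening of Sigma_l.

    Eigenvalues are sorted descending; filters are normalized so that
    w' Sigma_l w = 1; patterns are A = Sigma_l W = (W')^{-1}.
    """
    Sl, Sr = _as_matrix(cov_left), _as_matrix(cov_right)
    if Sl.shape != Sr.shape or Sl.shape[0] != Sl.shape[1]:
        raise ValueError("covariances must be square and of equal dimension")
    for name, S in (("left", Sl), ("right", Sr)):
        lo = float(np.linalg.eigvalsh(S)[0])
        if lo <= 0:
            raise ValueError(
                f"{name} covariance is not positive definite "
                f"(smallest eigenvalue {lo:.3e})")
    # scipy.linalg.eigh(a, b) whitens b by Cholesky and returns eigenvectors
    # with v' b v = I, i.e. exactly the w' Sigma_l w = 1 normalization
    vals, vecs = sp_linalg.eigh(Sr, Sl)
    order = np.argsort(vals)[::-1]
    vals, W = vals[order], vecs[:, order]
    A = Sl @ W
    W, A = _break_ties(vals, W, A)
    return SpatialFilterBank(filters=W, patterns=A, eigenvalues=vals)


def _break_ties(vals: np.ndarray, W: np.ndarray, A: np.ndarray):
    """Reorder tied-eigenvalue filters by largest-pattern channel index."""
    i = 0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[i]) <= EIGENVALUE_TIE_TOL:
            j += 1
        if j - i > 1:
            block = np.arange(i, j)
            key = [int(np.argmax(np.abs(A[:, k]))) for k in block]
            perm = block[np.argsort(key, kind="stable")]
            W[:, block] = W[:, perm]
            A[:, block] = A[:, perm]
        i = j
    return W, A


def apply_csp(bank: SpatialFilterBank, epochs: EpochSet,
              selected: np.ndarray | None = None) -> FeatureMatrix:
    """log10 variance of each spatially filtered signal, per trial.

    A zero-variance filtered signal yields -inf and is reported rather
    than silently clipped.
    """
    if bank.n_channels != epochs.n_channels:
        raise ValueError("filter bank dimension does not match channel count")
    idx = np.arange(bank.n_channels) if selected is None else np.asarray(selected)
    W = bank.filters[:, idx]
    raw, _ = trial_covariances(epochs)
    var = np.einsum("cj,tcd,dj->tj", W, raw, W, optimize=True)
    var = np.maximum(var, 0.0)       # w'Sw >= 0; clamp roundoff negatives
    with np.errstate(divide="ignore"):
        values = np.log10(var)
    if np.isneginf(values).any():
        bad = sorted(set(map(int, np.where(np.isneginf(values))[0])))
        import logging
        logging.getLogger(__name__).warning(
            "zero-variance filtered signal in trial(s) %s", bad)
    names = [f"csp{int(j)}" for j in idx]
    return FeatureMatrix(values=values, feature_names=names, kind="csp")


def discriminant_pair(bank: SpatialFilterBank) -> tuple[np.ndarray, np.ndarray]:
    """(CSP-L1, CSP-R1): patterns of the most discriminative filter per class.

    CSP-R1 is the pattern of the largest-eigenvalue filter (maximal
    right/left variance ratio); CSP-L1 that of the smallest. Pattern
    signs are arbitrary.
    """
    return bank.patterns[:, -1].copy(), bank.patterns[:, 0].copy()


def patterns_to_csv(bank: SpatialFilterBank, channel_labels, path) -> None:
    """Export pattern topographies as a channel -> value table for plotting."""
    df = pd.DataFrame(bank.patterns,
                      index=list(channel_labels)[:bank.n_channels],
                      columns=[f"csp{j}" for j in range(bank.n_channels)])
    df.index.name = "channel"
    df.to_csv(path)
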