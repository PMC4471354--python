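"""Significance and topography statistics for decoding results.

Binomial accuracy test: the chance probability of classifying at least k
of n trials correctly, from the exact binomial upper tail. Pattern
similarity: Spearman rank correlation between two 64-coefficient
topographies (pattern signs are arbitrary, so a sign-aligned coefficient
is reported alongside the raw one). Per-feature class differences:
pooled-variance two-sample Student t-tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

ALPHA = 0.05


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    chance: float
    p_value: float
    significant: bool


def binomial_significance(k: int, n: int, chance: float = 0.5) -> BinomialTestResult:
    """Exact upper-tail probability P(X >= k), X ~ Binomial(n, chance)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must lie strictly in (0, 1)")
    p = float(sp_stats.binom.sf(k - 1, n, chance))
    return BinomialTestResult(k=int(k), n=int(n), chance=float(chance),
                              p_value=p, significant=p < ALPHA)


@dataclass(frozen=True)
class PatternCorrelation:
    r: float
    n: int
    p_value: float
    sign_aligned_r: float


def spearman_correlation(a, b, exact: bool = False) -> PatternCorrelation:
    """Spearman rank correlation with average ranks for ties.

    The two-tailed p-value uses the t-approximation (adequate at the
    n = 64 channel count this is built for); ``exact=True`` enumerates
    the permutation null instead and is only allowed for n <= 10.
    Because CSP pattern signs are arbitrary, ``sign_aligned_r`` reports
    max(r(a, b), r(a, -b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, p = sp_stats.spearmanr(a, b)
    r_flip, _ = sp_stats.spearmanr(a, -b)
    if exact:
        if len(a) > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        p = _exact_spearman_p(a, b, r)
    return PatternCorrelation(r=float(r), n=len(a), p_value=float(p),
                              sign_aligned_r=float(max(r, r_flip)))


def _exact_spearman_p(a: np.ndarray, b: np.ndarray, observed: float) -> float:
    """Two-tailed permutation p by full enumeration of one vector's order."""
    rb = sp_stats.rankdata(b)
    count = 0
    total = 0
    for perm in itertools.permutations(sp_stats.rankdata(a)):
        r = np.corrcoef(perm, rb)[0, 1]
        count += abs(r) >= abs(observed) - 1e-12
        total += 1
    return count / total


def feature_class_ttest(features, labels, left_label="left",
                        right_label="right", welch: bool = False) -> pd.DataFrame:
    """Two-sample Student t-test (pooled variance) per feature, right vs left.

    Positive t means the feature is larger on right-attention trials.
    ``welch=True`` switches to the unequal-variance variant.
    """
    values = features.values if hasattr(features, "values") else np.asarray(features)
    names = getattr(features, "feature_names",
                    [f"f{i}" for i in range(values.shape[1])])
    labels = np.asarray(labels)
    right = values[labels == right_label]
    left = values[labels == left_label]
    if len(right) < 2 or len(left) < 2:
        raise ValueError("need >= 2 trials in each class")
    t, p = sp_stats.ttest_ind(right, left, equal_var=not welch, axis=0)
    return pd.DataFrame({"feature": names, "t": t, "p": p})


def _star(p: float) -> str:
    return "*" if p < ALPHA else ""


def build_report(results, correlations=None, t_tests=None,
                 out_dir=None, seeds=None) -> dict:
    """Assemble decoding/correlation/t-test tables; optionally write CSV+JSON.

    Stars mark results significant at alpha = 0.05. Output is a dict of
    DataFrames plus a JSON-ready summary; writing is deterministic, so a
    report regenerated from the same inputs is byte-identical.
    """
    if not results:
        raise ValueError("at least one decoding result required")
    rows = []
    for res in results:
        rows.append({"mode": res.mode, "accuracy": res.accuracy,
                     "k": res.k_correct, "n": res.n_trials,
                     "p_value": res.p_value, "star": _star(res.p_value),
                     "chosen_c": res.chosen_c,
                     "n_selected": len(res.selected_features)})
    decoding = pd.DataFrame(rows)
    tables = {"decoding": decoding}
    if correlations:
        tables["pattern_correlations"] = pd.DataFrame(
            [{"pair": name, "r": c.r, "r2": c.r ** 2, "n": c.n,
              "p_value": c.p_value, "sign_aligned_r": c.sign_aligned_r,
              "star": _star(c.p_value)} for name, c in correlations.items()])
    if t_tests is not None:
        tt = t_tests.copy()
        tt["star"] = [_star(p) for p in tt["p"]]
        tables["feature_t_tests"] = tt
    summary = {
        "decoding": decoding.to_dict(orient="records"),
        "seeds": seeds if seeds is not None else [],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    tables["summary"] = summary
    return tables
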