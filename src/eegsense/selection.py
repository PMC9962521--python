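"""Feature selection: two-test statistical screen, rank-correlation
filter, recursive elimination and L1-embedded selection.

The screen keeps a feature only if both a label-permutation test on the
group mean difference and a Mann-Whitney U test reject at alpha (no
multiple-testing correction — each feature is screened marginally).
The Spearman filter then removes, within each sub-band, the later of
any feature pair with |rho| >= threshold.  Wrapper (RFE) and embedded
(L1) reductions operate on what survives.  All stages only ever remove
features, and all are meant to be refit inside each cross-validation
training fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import RFE, SelectorMixin
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable


@dataclass
class SelectionResult:
    """Audit record of a selection stage (or pipeline of stages)."""

    retained: list
    dropped: dict = field(default_factory=dict)   # key -> reason
    p_values: pd.DataFrame | None = None          # permutation / mannwhitney
    ranking: dict | None = None                   # RFE rank per feature key
    provenance: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "retained": [list(k) if isinstance(k, tuple) else k
                         for k in self.retained],
            "dropped": {str(k): v for k, v in self.dropped.items()},
        }
        if self.p_values is not None:
            payload["p_values"] = {
                str(k): row.to_dict()
                for k, row in self.p_values.iterrows()
            }
        if self.ranking is not None:
            payload["ranking"] = {str(k): int(v) for k, v in self.ranking.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def _perm_null_stats(X: np.ndarray, y: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Null |mean(a) - mean(b)| for every column under label shuffles.

    One shared set of permutations is applied to all columns: each
    column's marginal null law is unchanged, and the shared draws make
    the screen O(n_perm * n * p) matrix work instead of per-column loops.
    """
    n = len(y)
    n_case = int(np.sum(y == 1))
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    case_idx = order[:, :n_case]
    ctrl_idx = order[:, n_case:]
    return np.abs(
        X[case_idx].mean(axis=1) - X[ctrl_idx].mean(axis=1)
    )  # (n_perm, p)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-group permutation p-value for |mean(a) - mean(b)|.

    p = (1 + #{null >= observed}) / (n_perm + 1); ties count as
    exceedances, so identical groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    rng = np.random.default_rng(seed)
    X = np.concatenate([a, b])[:, None]
    y = np.concatenate([np.ones(len(a), int), np.zeros(len(b), int)])
    observed = abs(a.mean() - b.mean())
    null = _perm_null_stats(X, y, n_perm, rng)[:, 0]
    return float((1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1))


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p.

    Exact enumeration when the combined sample is small (n <= 10) and
    tie-free; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least 1 value")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


class TwoTestScreen(SelectorMixin, BaseEstimator):
    """Keep features significant under both the permutation and U tests."""

    def __init__(self, alpha: float = 0.05, n_perm: int = 10_000,
                 seed: int | None = 0):
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, y):
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both groups must be present")
        y_bin = (y == np.max(y)).astype(int)
        case, ctrl = X[y_bin == 1], X[y_bin == 0]
        rng = np.random.default_rng(self.seed)
        null = _perm_null_stats(X, y_bin, self.n_perm, rng)
        observed = np.abs(case.mean(axis=0) - ctrl.mean(axis=0))
        p_perm = (1 + np.sum(null >= observed[None, :] - 1e-12, axis=0)) / (
            self.n_perm + 1
        )
        p_mw = np.array(
            [mann_whitney_u(case[:, j], ctrl[:, j])[1] for j in range(X.shape[1])]
        )
        self.p_perm_ = p_perm
        self.p_mw_ = p_mw
        self.support_ = (p_perm < self.alpha) & (p_mw < self.alpha)
        self.feature_keys_ = cols
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


def two_test_screen(table: FeatureTable, alpha: float = 0.05,
                    n_perm: int = 10_000, seed: int | None = 0) -> SelectionResult:
    """Apply :class:`TwoTestScreen` to a feature table."""
    y = (table.groups == "case").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be present")
    filled = table.fill_normalized().impute_median()
    screen = TwoTestScreen(alpha=alpha, n_perm=n_perm, seed=seed)
    screen.fit(filled.data, y)
    cols = list(filled.data.columns)
    retained = [c for c, keep in zip(cols, screen.support_) if keep]
    dropped = {
        c: f"p_perm={pp:.4g}, p_mw={pm:.4g} not both < {alpha}"
        for c, keep, pp, pm in zip(cols, screen.support_,
                                   screen.p_perm_, screen.p_mw_)
        if not keep
    }
    pvals = pd.DataFrame(
        {"permutation": screen.p_perm_, "mannwhitney": screen.p_mw_},
        index=pd.Index(cols),
    )
    return SelectionResult(retained, dropped, pvals,
                           provenance=f"two_test_screen(alpha={alpha})")


class SpearmanFilter(SelectorMixin, BaseEstimator):
    """Drop the later of any highly rank-correlated feature pair.

    Pairs are compared within groups (the sub-band, when the input is a
    feature-table DataFrame) in column order, so the result is
    deterministic.  Constant columns have undefined rho, treated as 0.
    """

    def __init__(self, threshold: float = 0.8, groups: list | None = None):
        self.threshold = threshold
        self.groups = groups

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns)
            if self.groups is None and isinstance(X.columns, pd.MultiIndex):
                group_of = [c[1] for c in cols]  # band level
            else:
                group_of = self.groups or [0] * len(cols)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            cols = list(range(X.shape[1]))
            group_of = self.groups or [0] * len(cols)
        keep = np.ones(len(cols), dtype=bool)
        dropped_because: dict = {}
        rank = pd.DataFrame(X).rank().to_numpy()
        for g in dict.fromkeys(group_of):
            idx = [j for j, gj in enumerate(group_of) if gj == g]
            for pos, j in enumerate(idx):
                if not keep[j]:
                    continue
                for i in idx[:pos]:
                    if not keep[i]:
                        continue
                    rho = _spearman(rank[:, i], rank[:, j])
                    if abs(rho) >= self.threshold:
                        keep[j] = False
                        dropped_because[cols[j]] = (
                            f"|rho|={abs(rho):.3f} >= {self.threshold} "
                            f"with {cols[i]}"
                        )
                        break
        self.support_ = keep
        self.dropped_ = dropped_because
        self.feature_keys_ = cols
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


def _spearman(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    sx, sy = np.std(rank_x), np.std(rank_y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(rank_x, rank_y)[0, 1])


def spearman_filter(table: FeatureTable, threshold: float = 0.8) -> SelectionResult:
    filled = table.fill_normalized().impute_median()
    filt = SpearmanFilter(threshold=threshold)
    filt.fit(filled.data)
    retained = [c for c, keep in zip(filt.feature_keys_, filt.support_) if keep]
    return SelectionResult(retained, dict(filt.dropped_),
                           provenance=f"spearman_filter(threshold={threshold})")


_RFE_ESTIMATORS = {
    "logistic": lambda seed: LogisticRegression(max_iter=5000),
    "perceptron": lambda seed: Perceptron(random_state=seed),
    "tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "svm": lambda seed: LinearSVC(max_iter=20_000),
}


def rfe(
    table_or_df,
    labels,
    estimator: str = "logistic",
    n_target: int = 1,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination, one feature per iteration."""
    if isinstance(table_or_df, FeatureTable):
        df = table_or_df.fill_normalized().impute_median().data
    else:
        df = pd.DataFrame(table_or_df)
    if n_target < 1 or n_target > df.shape[1]:
        raise ValueError(
            f"n_target must be in [1, {df.shape[1]}], got {n_target}"
        )
    if estimator not in _RFE_ESTIMATORS:
        raise ValueError(f"estimator must be one of {sorted(_RFE_ESTIMATORS)}")
    y = np.asarray(labels)
    sel = RFE(_RFE_ESTIMATORS[estimator](seed), n_features_to_select=n_target,
              step=1)
    sel.fit(df.to_numpy(dtype=float), y)
    cols = list(df.columns)
    retained = [c for c, keep in zip(cols, sel.support_) if keep]
    ranking = dict(zip(cols, sel.ranking_))
    dropped = {c: f"eliminated at rank {ranking[c]}"
               for c in cols if c not in retained}
    return SelectionResult(retained, dropped, ranking=ranking,
                           provenance=f"rfe({estimator}, n_target={n_target})")


def embedded_l1(table_or_df, labels, strength: float = 1.0) -> SelectionResult:
    """L1-regularised selection: features with zero coefficient are dropped.

    ``strength`` is the penalty weight (sklearn's C = 1/strength).
    """
    if isinstance(table_or_df, FeatureTable):
        df = table_or_df.fill_normalized().impute_median().data
    else:
        df = pd.DataFrame(table_or_df)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if strength <= 0:
        raise ValueError("strength must be positive")
    model = LogisticRegression(
        penalty="l1", solver="liblinear", C=1.0 / strength, max_iter=5000
    )
    model.fit(df.to_numpy(dtype=float), y)
    coef = model.coef_.ravel()
    cols = list(df.columns)
    retained = [c for c, w in zip(cols, coef) if w != 0.0]
    dropped = {c: "coefficient shrunk to 0"
               for c, w in zip(cols, coef) if w == 0.0}
    return SelectionResult(retained, dropped,
                           provenance=f"embedded_l1(strength={strength})")
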