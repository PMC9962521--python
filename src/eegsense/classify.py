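"""Threshold and machine-learning classifiers with native decision
evaluation, stratified k-fold evaluation and the confusion-matrix
metric suite.

Model fitting for the linear SVM, logistic regression and decision
tree delegates to scikit-learn, but the decision side — the linear
score w.x + b, the sigmoid probability and the if-then tree walk — is
evaluated natively from extracted parameters, mirroring an on-node
deployment where only coefficients or rules live on the sensor.  The
threshold classifier compares each feature against a statistic (mean,
min, max, median or histogram mode) of the case-group training values,
optionally gated by a feature that was 100% PPV- or NPV-pure on the
training folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

MODEL_KINDS = ("threshold", "svm_linear", "logreg", "tree")
THRESHOLD_STATISTICS = ("mean", "min", "max", "median", "mode")

#: hyperparameter grids for tuning (linear-kernel SVM C sweep; logistic
#: regression solver x C; decision-tree criterion x splitter; threshold
#: statistic sweep)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm_linear": [{"C": c} for c in (0.01, 0.1, 1, 10, 100)],
    "logreg": [
        {"solver": s, "C": c}
        for s in ("liblinear", "newton-cg", "lbfgs")
        for c in (0.01, 0.1, 1, 10, 100)
    ],
    "tree": [
        {"criterion": c, "splitter": s}
        for c in ("gini", "entropy")
        for s in ("random", "best")
    ],
    "threshold": [{"statistic": s} for s in THRESHOLD_STATISTICS],
}


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvalReport:
    """Confusion counts and derived metrics (percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spec: float
    ppv: float
    npv: float
    f1: float
    per_fold: list = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> dict[str, float]:
        """Metrics rounded to 2 decimals for display."""
        return {k: round(getattr(self, k), 2)
                for k in ("acc", "sen", "spec", "ppv", "npv", "f1")}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": {"tp": self.tp, "fp": self.fp,
                       "tn": self.tn, "fn": self.fn},
            "metrics": self.rounded(),
            "per_fold": self.per_fold,
            "hyperparams": self.hyperparams,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _safe_ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def f1_from_sen_ppv(sen: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV, both given in percent."""
    if sen + ppv == 0:
        return float("nan")
    return 2.0 * sen * ppv / (sen + ppv)


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 (percent).

    Zero-denominator metrics (e.g. PPV with no positive predictions)
    come back as NaN rather than raising.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    sen = _safe_ratio(tp, tp + fn)
    ppv = _safe_ratio(tp, tp + fp)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=_safe_ratio(tp + tn, tp + fp + tn + fn),
        sen=sen,
        spec=_safe_ratio(tn, tn + fp),
        ppv=ppv,
        npv=_safe_ratio(tn, tn + fn),
        f1=f1_from_sen_ppv(sen, ppv),
    )


def impurity(p: np.ndarray, criterion: str = "gini") -> float:
    """Split impurity of a class-probability vector.

    entropy = -sum p log2 p (bits); gini = 1 - sum p^2.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    if criterion == "gini":
        return float(1.0 - np.sum(p ** 2))
    if criterion == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log2(nz)))
    raise ValueError("criterion must be 'gini' or 'entropy'")


# ---------------------------------------------------------------------------
# native decision evaluation

def linear_decision(w: np.ndarray, b: float, x: np.ndarray) -> tuple[float, int]:
    """Linear score w.x + b; label case (1) iff score > 0, ties -> control."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"dimension mismatch: w{w.shape} vs x{x.shape}")
    score = float(w @ x + b)
    return score, int(score > 0)


def logistic_prob(w: np.ndarray, b: float, x: np.ndarray) -> float:
    """Sigmoid of the linear score: 1 / (1 + exp(-(w.x + b)))."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"dimension mismatch: w{w.shape} vs x{x.shape}")
    z = float(w @ x + b)
    with np.errstate(over="ignore"):
        return float(1.0 / (1.0 + np.exp(-z)))


def _tree_to_rules(tree, feature_index_map: list[int]) -> dict:
    """Convert a fitted sklearn tree into a nested if-then dict."""
    t = tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            label = int(tree.classes_[int(np.argmax(t.value[i]))])
            return {"label": label}
        return {
            "feature": feature_index_map[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),    # x <= threshold
            "right": node(t.children_right[i]),
        }

    return node(0)


def _eval_rules(rules: dict, x: np.ndarray) -> int:
    node = rules
    while "label" not in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return int(node["label"])


# ---------------------------------------------------------------------------
# threshold classifier

def _histogram_mode(values: np.ndarray, bins: int = 16) -> float:
    """Mode of continuous values: midpoint of the fullest equal-width bin."""
    values = np.asarray(values, dtype=float)
    if np.min(values) == np.max(values):
        return float(values[0])
    counts, edges = np.histogram(values, bins=bins)
    j = int(np.argmax(counts))
    return float((edges[j] + edges[j + 1]) / 2.0)


def _case_statistic(values: np.ndarray, statistic: str, bins: int = 16) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "min":
        return float(np.min(values))
    if statistic == "max":
        return float(np.max(values))
    if statistic == "median":
        return float(np.median(values))
    if statistic == "mode":
        return _histogram_mode(values, bins)
    raise ValueError(f"statistic must be one of {THRESHOLD_STATISTICS}")


def _rule_predict(col: np.ndarray, threshold: float, direction: int) -> np.ndarray:
    """direction +1: case iff value >= threshold; -1: case iff value <= threshold."""
    return (col >= threshold).astype(int) if direction > 0 else (
        col <= threshold
    ).astype(int)


class ThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold rule with optional purity gate.

    fit learns, for every feature, the chosen statistic of the
    case-group values as a threshold and the crossing direction that
    maximises training accuracy; prediction uses the best single
    feature.  With ``use_gate=True`` a secondary feature whose rule is
    100% PPV- or NPV-pure on the training data fires first: when it
    claims its pure label the primary rule is bypassed.
    """

    def __init__(self, statistic: str = "mean", use_gate: bool = False,
                 bins: int = 16):
        self.statistic = statistic
        self.use_gate = use_gate
        self.bins = bins

    def fit(self, X, y):
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not ((y == 1).any() and (y == 0).any()):
            raise ValueError("both classes must be present in training data")
        case = X[y == 1]
        n_feat = X.shape[1]
        thresholds = np.empty(n_feat)
        directions = np.empty(n_feat, dtype=int)
        accs = np.empty(n_feat)
        for j in range(n_feat):
            t = _case_statistic(case[:, j], self.statistic, self.bins)
            acc_ge = float(np.mean(_rule_predict(X[:, j], t, +1) == y))
            acc_le = float(np.mean(_rule_predict(X[:, j], t, -1) == y))
            thresholds[j] = t
            directions[j] = +1 if acc_ge >= acc_le else -1
            accs[j] = max(acc_ge, acc_le)
        self.thresholds_ = thresholds
        self.directions_ = directions
        self.train_accuracy_ = accs
        self.primary_ = int(np.argmax(accs))
        self.gate_ = self._find_gate(X, y) if self.use_gate else None
        self.feature_keys_ = cols
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_feat
        return self

    def _find_gate(self, X: np.ndarray, y: np.ndarray) -> dict | None:
        """First feature (table order) whose rule is PPV- or NPV-pure."""
        for j in range(X.shape[1]):
            if j == self.primary_:
                continue
            pred = _rule_predict(X[:, j], self.thresholds_[j],
                                 self.directions_[j])
            pos, neg = pred == 1, pred == 0
            if pos.any() and np.all(y[pos] == 1):   # 100% PPV
                return {"feature": j, "threshold": float(self.thresholds_[j]),
                        "direction": int(self.directions_[j]),
                        "fire_on": 1}
            if neg.any() and np.all(y[neg] == 0):   # 100% NPV
                return {"feature": j, "threshold": float(self.thresholds_[j]),
                        "direction": int(self.directions_[j]),
                        "fire_on": 0}
        return None

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        pred = _rule_predict(X[:, self.primary_],
                             self.thresholds_[self.primary_],
                             self.directions_[self.primary_])
        if self.gate_ is not None:
            g = self.gate_
            gate_pred = _rule_predict(X[:, g["feature"]], g["threshold"],
                                      g["direction"])
            fires = gate_pred == g["fire_on"]
            pred = np.where(fires, g["fire_on"], pred)
        return pred


def threshold_train(X, y, statistic: str = "mean",
                    use_gate: bool = False) -> "TrainedModel":
    """Fit a threshold rule and wrap it as a :class:`TrainedModel`."""
    clf = ThresholdClassifier(statistic=statistic, use_gate=use_gate).fit(X, y)
    keys = clf.feature_keys_ or list(range(clf.n_features_in_))
    return TrainedModel(
        kind="threshold",
        feature_keys=keys,
        thresholds=clf.thresholds_.tolist(),
        directions=clf.directions_.tolist(),
        primary=clf.primary_,
        gate=clf.gate_,
        metadata={"statistic": statistic, "use_gate": use_gate,
                  "train_accuracy": clf.train_accuracy_.tolist()},
    )


def threshold_predict_combined(model: "TrainedModel", row) -> int:
    """Gate-then-primary decision for one feature row (mapping or Series)."""
    def value(idx: int) -> float:
        key = model.feature_keys[idx]
        try:
            return float(row[key])
        except (KeyError, IndexError, TypeError):
            raise KeyError(f"feature {key!r} missing from row") from None

    if model.gate is not None:
        g = model.gate
        fired = int(_rule_predict(np.array([value(g["feature"])]),
                                  g["threshold"], g["direction"])[0])
        if fired == g["fire_on"]:
            return g["fire_on"]
    p = model.primary
    return int(_rule_predict(np.array([value(p)]),
                             model.thresholds[p], model.directions[p])[0])


# ---------------------------------------------------------------------------
# trained-model container

@dataclass
class TrainedModel:
    """Classifier parameters sufficient for native decision evaluation.

    Linear kinds carry (weights, bias); trees carry a nested if-then
    rule dict; the threshold kind carries per-feature thresholds and
    directions plus the primary rule index and optional gate.
    """

    kind: str
    feature_keys: list
    weights: list[float] | None = None
    bias: float | None = None
    rules: dict | None = None
    thresholds: list[float] | None = None
    directions: list[int] | None = None
    primary: int | None = None
    gate: dict | None = None
    metadata: dict = field(default_factory=dict)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_keys].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_keys):
            raise ValueError(
                f"expected {len(self.feature_keys)} features, got {X.shape[1]}"
            )
        return X

    def decision_scores(self, X) -> np.ndarray:
        if self.kind not in ("svm_linear", "logreg"):
            raise ValueError(f"no linear scores for kind {self.kind!r}")
        M = self._matrix(X)
        return M @ np.asarray(self.weights) + self.bias

    def predict(self, X) -> np.ndarray:
        M = self._matrix(X)
        if self.kind == "svm_linear":
            return (self.decision_scores(M) > 0).astype(int)
        if self.kind == "logreg":
            scores = self.decision_scores(M)
            with np.errstate(over="ignore"):
                probs = 1.0 / (1.0 + np.exp(-scores))
            return (probs >= 0.5).astype(int)
        if self.kind == "tree":
            return np.array([_eval_rules(self.rules, x) for x in M])
        if self.kind == "threshold":
            pred = _rule_predict(M[:, self.primary],
                                 self.thresholds[self.primary],
                                 self.directions[self.primary])
            if self.gate is not None:
                g = self.gate
                gp = _rule_predict(M[:, g["feature"]], g["threshold"],
                                   g["direction"])
                pred = np.where(gp == g["fire_on"], g["fire_on"], pred)
            return pred
        raise ValueError(f"unknown model kind {self.kind!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "feature_keys": [list(k) if isinstance(k, tuple) else k
                             for k in self.feature_keys],
            "weights": self.weights,
            "bias": self.bias,
            "rules": self.rules,
            "thresholds": self.thresholds,
            "directions": self.directions,
            "primary": self.primary,
            "gate": self.gate,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        d = json.loads(text)
        d["feature_keys"] = [tuple(k) if isinstance(k, list) else k
                             for k in d["feature_keys"]]
        return cls(**d)


def train_model(X, y, kind: str, seed: int = 0,
                feature_keys: list | None = None, **hyper) -> TrainedModel:
    """Fit one classifier and extract its native decision parameters."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"kind must be one of {MODEL_KINDS}")
    keys = feature_keys
    if isinstance(X, pd.DataFrame):
        keys = keys or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    keys = keys or list(range(X.shape[1]))

    if kind == "threshold":
        model = threshold_train(X, y, **hyper)
        model.feature_keys = keys
        return model
    if kind == "svm_linear":
        est = SVC(kernel="linear", C=hyper.get("C", 1.0))
    elif kind == "logreg":
        est = LogisticRegression(solver=hyper.get("solver", "liblinear"),
                                 C=hyper.get("C", 1.0), max_iter=10_000)
    else:
        est = DecisionTreeClassifier(
            criterion=hyper.get("criterion", "gini"),
            splitter=hyper.get("splitter", "best"),
            random_state=seed,
        )
    est.fit(X, y)
    meta = {"hyperparams": dict(hyper), "seed": seed}
    if kind == "tree":
        return TrainedModel(kind=kind, feature_keys=keys,
                            rules=_tree_to_rules(est, list(range(X.shape[1]))),
                            metadata=meta)
    return TrainedModel(kind=kind, feature_keys=keys,
                        weights=est.coef_.ravel().tolist(),
                        bias=float(est.intercept_[0]), metadata=meta)


# ---------------------------------------------------------------------------
# cross-validated grid search

def _rfe_order(train_df: pd.DataFrame, y_train, model_kind: str,
               seed: int) -> list:
    """Full recursive-elimination order (best-ranked first).

    With one feature eliminated per iteration the rank-k prefix of the
    order is exactly the subset RFE would select at n_target = k, so a
    single run serves every candidate size.
    """
    from .selection import rfe as run_rfe

    est = {"svm_linear": "svm", "logreg": "logistic",
           "tree": "tree", "threshold": "logistic"}[model_kind]
    res = run_rfe(train_df, y_train, estimator=est, n_target=1, seed=seed)
    return sorted(res.ranking, key=res.ranking.get)


def _fold_feature_keys(table: FeatureTable, train_ids, y_train,
                       screen_alpha: float, screen_n_perm: int,
                       spearman_threshold: float, rfe_n: int | None,
                       model_kind: str, seed: int) -> tuple[FeatureTable, list]:
    """Selection pipeline refit on one training fold.

    Returns the fold-normalised table (train-fit normalisation,
    imputation and min-max column scaling applied to all rows) and the
    retained feature keys.  Min-max scaling of every column (fit on the
    training rows, applied unclipped to the rest) puts band powers,
    coefficient variances and entropies on a common scale for the
    linear fits.
    """
    from .selection import SpearmanFilter, TwoTestScreen, rfe as run_rfe

    filled = table.fill_normalized(train_ids).impute_median(train_ids)
    lo = filled.data.loc[train_ids].min()
    hi = filled.data.loc[train_ids].max()
    span = (hi - lo).replace(0.0, np.nan)
    scaled = ((filled.data - lo) / span).fillna(0.0)  # constant cols inert
    filled = FeatureTable(scaled, filled.groups)
    train_df = filled.data.loc[train_ids]
    screen = TwoTestScreen(alpha=screen_alpha, n_perm=screen_n_perm, seed=seed)
    screen.fit(train_df, y_train)
    keys = [c for c, keep in zip(train_df.columns, screen.support_) if keep]
    if not keys:  # degenerate fold: keep the single least-null feature
        j = int(np.argmin(screen.p_perm_ + screen.p_mw_))
        keys = [train_df.columns[j]]
    filt = SpearmanFilter(threshold=spearman_threshold)
    filt.fit(train_df[keys])
    keys = [c for c, keep in zip(keys, filt.support_) if keep]
    if isinstance(rfe_n, int) and rfe_n < len(keys):
        est = {"svm_linear": "svm", "logreg": "logistic",
               "tree": "tree", "threshold": "logistic"}[model_kind]
        res = run_rfe(train_df[keys], y_train, estimator=est,
                      n_target=rfe_n, seed=seed)
        keys = res.retained
    return filled, keys, lo, hi


def _unscale_model(model: TrainedModel, lo: np.ndarray,
                   hi: np.ndarray) -> TrainedModel:
    """Fold min-max feature scaling back into the model parameters.

    The fitted model operates on scaled features x' = (x - lo)/(hi - lo);
    rewriting weights, biases and split/decision thresholds in raw
    feature units gives a model that consumes raw feature values
    directly, as an embedded deployment would.  Exact: the decision
    function is unchanged.
    """
    lo = np.asarray(lo, dtype=float)
    span = np.asarray(hi, dtype=float) - lo
    degenerate = span <= 0
    span_safe = np.where(degenerate, 1.0, span)
    if model.kind in ("svm_linear", "logreg"):
        w = np.asarray(model.weights, dtype=float)
        w_raw = np.where(degenerate, 0.0, w / span_safe)
        model.bias = float(model.bias - np.sum(w_raw * lo))
        model.weights = w_raw.tolist()
    elif model.kind == "tree":
        def unscale(node: dict) -> None:
            if "label" in node:
                return
            j = node["feature"]
            node["threshold"] = float(lo[j] + node["threshold"] * span_safe[j])
            unscale(node["left"])
            unscale(node["right"])
        unscale(model.rules)
    elif model.kind == "threshold":
        t = np.asarray(model.thresholds, dtype=float)
        model.thresholds = (lo + t * span_safe).tolist()
        if model.gate is not None:
            j = model.gate["feature"]
            model.gate["threshold"] = float(
                lo[j] + model.gate["threshold"] * span_safe[j]
            )
    model.metadata["feature_space"] = "raw"
    return model


def grid_search_cv(
    table: FeatureTable,
    labels=None,
    model_kind: str = "svm_linear",
    grid: list[dict] | None = None,
    k: int = 5,
    seed: int = 0,
    screen_alpha: float = 0.05,
    screen_n_perm: int = 2000,
    spearman_threshold: float = 0.8,
    rfe_n: int | str | None = "all",
    max_rfe_size: int = 30,
) -> tuple[TrainedModel, EvalReport]:
    """Stratified subject-level k-fold hyperparameter search.

    Normalisation, imputation and the selection pipeline are refit on
    every training fold.  ``rfe_n='all'`` (the default) sweeps every
    recursive-elimination subset size up to ``max_rfe_size`` as part of
    the grid, mirroring a search over each possible number of features;
    an int fixes the size, None disables RFE.  The best (hyperparameter,
    size) combination by mean fold accuracy — smaller subsets win ties —
    is refit on the full table and returned with an :class:`EvalReport`
    (confusion counts pooled over folds, per-fold breakdown attached).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    grid = grid or DEFAULT_GRIDS[model_kind]
    y = (np.asarray(labels, dtype=int) if labels is not None
         else (table.groups == "case").astype(int).to_numpy())
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} subjects per class for {k}-fold CV, "
            f"got {counts.tolist()}"
        )
    sweep_sizes = rfe_n == "all"
    sizes = list(range(1, max_rfe_size + 1)) if sweep_sizes else [None]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_results: dict[tuple[int, int | None], list[dict]] = {
        (gi, s): [] for gi in range(len(grid)) for s in sizes
    }
    for fold_no, (tr, te) in enumerate(skf.split(table.data, y)):
        train_ids = table.data.index[tr]
        filled, keys, _lo, _hi = _fold_feature_keys(
            table, train_ids, y[tr], screen_alpha, screen_n_perm,
            spearman_threshold, None if sweep_sizes else rfe_n,
            model_kind, seed,
        )
        order = (_rfe_order(filled.data.loc[train_ids, keys], y[tr],
                            model_kind, seed)
                 if sweep_sizes and len(keys) > 1 else keys)
        yt = y[te]
        for s in sizes:
            fold_keys = keys if s is None else order[: min(s, len(order))]
            X_train = filled.data.loc[train_ids, fold_keys]
            X_test = filled.data.iloc[te][fold_keys]
            for gi, hyper in enumerate(grid):
                model = train_model(X_train, y[tr], model_kind, seed=seed,
                                    **hyper)
                pred = model.predict(X_test)
                fold_results[(gi, s)].append({
                    "fold": fold_no,
                    "tp": int(np.sum((pred == 1) & (yt == 1))),
                    "fp": int(np.sum((pred == 1) & (yt == 0))),
                    "tn": int(np.sum((pred == 0) & (yt == 0))),
                    "fn": int(np.sum((pred == 0) & (yt == 1))),
                    "n_features": len(fold_keys),
                })
    def mean_acc(folds: list[dict]) -> float:
        return float(np.mean([
            (f["tp"] + f["tn"])
            / max(f["tp"] + f["fp"] + f["tn"] + f["fn"], 1)
            for f in folds
        ]))

    accs = {key: mean_acc(folds) for key, folds in fold_results.items()}
    # iteration order is grid-major then size-ascending, so ties resolve
    # to the earliest hyperparameter row and the smallest feature subset
    best_key = max(accs, key=lambda kk: (accs[kk],))
    for kk in fold_results:
        if accs[kk] == accs[best_key]:
            best_key = kk
            break
    best_gi, best_size = best_key
    folds = fold_results[best_key]
    report = metrics_from_confusion(
        sum(f["tp"] for f in folds), sum(f["fp"] for f in folds),
        sum(f["tn"] for f in folds), sum(f["fn"] for f in folds),
    )
    report.per_fold = folds
    report.hyperparams = dict(grid[best_gi])
    if best_size is not None:
        report.hyperparams["n_features"] = best_size
    filled, keys, lo, hi = _fold_feature_keys(
        table, table.data.index, y, screen_alpha, screen_n_perm,
        spearman_threshold, None if sweep_sizes else rfe_n,
        model_kind, seed,
    )
    if sweep_sizes and len(keys) > 1:
        order = _rfe_order(filled.data[keys], y, model_kind, seed)
        keys = order[: min(best_size, len(order))]
    final = train_model(filled.data[keys], y, model_kind, seed=seed,
                        **grid[best_gi])
    final = _unscale_model(final, lo[keys].to_numpy(), hi[keys].to_numpy())
    final.metadata.update({"cv_mean_accuracy": accs[best_key],
                           "k": k, "seed": seed})
    return final, report
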