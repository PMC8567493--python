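"""Model core: balanced down-sampling, mRMR, regularized boosted-linear fits.

The classifier is gradient boosting with *linear* base learners (XGBoost
``gblinear``), the only booster that directly yields per-feature aggregate
linear coefficients; features are standardized on the training split so the
coefficient-magnitude retention rule (|c| > 0.2) is unit-free.  A tree
booster is available behind the same contract; its "coefficients" are then a
least-squares linear surrogate of the boosted margin and are documented as
such.

Evaluation follows the study workflow: repeated random down-sampling to a
class-balanced subset, mRMR feature reduction, stratified k-fold
cross-validation, and metrics on the pooled held-out scores, averaged over
repeats.  Everything is deterministic under a seed (single-threaded
coordinate-descent updater).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .metrics import ClassMetrics, ModelEval, auc, class_metrics

__all__ = [
    "BoosterParams",
    "FittedClassifier",
    "downsample_balance",
    "mrmr_select",
    "fit_classifier",
    "cross_validated_eval",
    "extract_importances",
    "averaged_importances",
]


@dataclass(frozen=True)
class BoosterParams:
    """Knobs of the regularized boosted classifier.

    Defaults: linear base learners, 200 rounds, step-size shrinkage
    eta = 0.1, L1 = 0.1, L2 = 1.0.  Tree mode restricts depth to 3 with
    minimum split loss gamma = 1.
    """

    booster_kind: str = "linear"  # "linear" | "tree"
    n_rounds: int = 200
    learning_rate: float = 0.1
    l1_weight: float = 0.02
    l2_weight: float = 0.2
    max_depth: int = 3
    min_split_loss: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if min(self.l1_weight, self.l2_weight, self.min_split_loss) < 0:
            raise ValueError("regularization penalties must be non-negative")
        if self.n_rounds < 1 or self.max_depth < 1:
            raise ValueError("n_rounds and max_depth must be positive")
        if self.booster_kind not in ("linear", "tree"):
            raise ValueError("booster_kind must be 'linear' or 'tree'")


def downsample_balance(
    table: pd.DataFrame, label_column: str, seed: int
) -> pd.DataFrame:
    """Random down-sampling (without replacement) to the minority-class count."""
    labels = table[label_column]
    counts = labels.value_counts()
    if counts.size < 2:
        raise ValueError("down-sampling requires both classes present")
    if (counts == 0).any():
        raise ValueError("a class is empty")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    picked = []
    for cls in sorted(counts.index):
        idx = table.index[labels == cls].to_numpy()
        picked.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.concatenate(picked)
    return table.loc[np.sort(keep)]


def _discretize(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` codes.

    Columns with few distinct values (binary flags, categories) keep their
    own codes; quantile binning would collapse them into a single bin.
    """
    if np.unique(values).size <= n_bins:
        return pd.factorize(values)[0]
    binned = pd.qcut(values, n_bins, labels=False, duplicates="drop")
    return np.nan_to_num(binned, nan=0.0).astype(int)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats between two small integer code vectors (contingency based)."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(
    features: pd.DataFrame, labels, k: int, n_bins: int = 4
) -> list[str]:
    """Greedy minimum-redundancy / maximum-relevance feature selection.

    Score of a candidate = MI(feature; label) − mean MI(feature; selected),
    with mutual information estimated on equal-frequency 4-bin codes (the
    MID variant).  Ties break by column order.  ``k >= n_features`` returns
    every feature in greedy order.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    cols = list(features.columns)
    y_codes = pd.factorize(np.asarray(labels))[0]
    codes = {c: _discretize(features[c].to_numpy(dtype=float), n_bins) for c in cols}
    relevance = np.array([_mutual_information(codes[c], y_codes) for c in cols])
    selected: list[str] = []
    remaining = list(range(len(cols)))
    redundancy = np.zeros(len(cols))
    while remaining and len(selected) < min(k, len(cols)):
        scores = np.array(
            [
                relevance[i] - (redundancy[i] / len(selected) if selected else 0.0)
                for i in remaining
            ]
        )
        best = remaining[int(np.argmax(scores))]  # argmax keeps first max: column-order ties
        selected.append(cols[best])
        remaining.remove(best)
        for i in remaining:  # accumulate MI against the newly selected feature
            redundancy[i] += _mutual_information(codes[cols[i]], codes[cols[best]])
    return selected


class FittedClassifier:
    """A fitted boosted classifier with standardized-feature linear coefficients."""

    def __init__(
        self,
        booster: xgb.Booster,
        feature_names: list[str],
        mean: np.ndarray,
        scale: np.ndarray,
        params: BoosterParams,
        coefficients: pd.Series,
    ):
        self._booster = booster
        self.feature_names = feature_names
        self._mean = mean
        self._scale = scale
        self.params = params
        self._coefficients = coefficients

    @property
    def coefficients(self) -> pd.Series:
        """Aggregate per-feature linear coefficients on standardized inputs."""
        return self._coefficients.copy()

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.feature_names].to_numpy(dtype=float)
        return (Z - self._mean) / self._scale

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        dm = xgb.DMatrix(self._transform(X), feature_names=self.feature_names)
        return self._booster.predict(dm)

    def predict(self, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _linear_coefficients(booster: xgb.Booster, feature_names: list[str]) -> pd.Series:
    dump = booster.get_dump()[0]
    lines = [ln.strip() for ln in dump.splitlines() if ln.strip()]
    w_start = lines.index("weight:") + 1
    weights = [float(v) for v in lines[w_start : w_start + len(feature_names)]]
    return pd.Series(weights, index=feature_names, dtype=float)


def fit_classifier(
    X: pd.DataFrame, y, params: BoosterParams | None = None
) -> FittedClassifier:
    """Fit the regularized boosted classifier on (internally standardized) features."""
    params = params or BoosterParams()
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValueError(f"NaN values in feature {bad!r}")
    y = np.asarray(y, dtype=int)
    feature_names = list(X.columns)
    Z = X.to_numpy(dtype=float)
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - mean) / scale

    common = {
        "objective": "binary:logistic",
        "eta": params.learning_rate,
        "alpha": params.l1_weight,
        "lambda": params.l2_weight,
        "nthread": 1,
        "seed": params.seed,
    }
    if params.booster_kind == "linear":
        xgb_params = {
            **common,
            "booster": "gblinear",
            "updater": "coord_descent",
            "feature_selector": "cyclic",
        }
    else:
        xgb_params = {
            **common,
            "booster": "gbtree",
            "max_depth": params.max_depth,
            "gamma": params.min_split_loss,
            "tree_method": "exact",
        }
    dtrain = xgb.DMatrix(Zs, label=y, feature_names=feature_names)
    booster = xgb.train(xgb_params, dtrain, num_boost_round=params.n_rounds)

    if params.booster_kind == "linear":
        coef = _linear_coefficients(booster, feature_names)
    else:
        # linear surrogate of the boosted margin, so the same retention rule applies
        margin = booster.predict(dtrain, output_margin=True)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([Zs, np.ones(len(Zs))]), margin, rcond=None
        )
        coef = pd.Series(beta[:-1], index=feature_names, dtype=float)
    return FittedClassifier(booster, feature_names, mean, scale, params, coef)


def cross_validated_eval(
    table: pd.DataFrame,
    feature_columns: list[str],
    label_column: str,
    params: BoosterParams | None = None,
    cv_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    mrmr_k: int | None = 15,
) -> ModelEval:
    """Repeated balanced-down-sampling + stratified k-fold evaluation.

    Each repeat draws a balanced subset, optionally reduces it to ``mrmr_k``
    features, and pools held-out scores from a stratified k-fold; AUC,
    accuracy (0.5 threshold) and per-class precision/sensitivity are computed
    per repeat and averaged.  Per-class F-1 is the harmonic mean of the
    averaged precision/sensitivity.
    """
    params = params or BoosterParams()
    labels = table[label_column]
    counts = labels.value_counts()
    if counts.size != 2:
        raise ValueError("evaluation requires exactly two classes")
    if counts.min() < cv_folds:
        raise ValueError(
            f"minority class has {counts.min()} members, fewer than cv_folds="
            f"{cv_folds}; reduce cv_folds"
        )
    aucs, accs = [], []
    pr = {0: [], 1: []}
    se = {0: [], 1: []}
    for r in range(n_repeats):
        rseed = seed + r
        balanced = downsample_balance(table, label_column, rseed).reset_index(drop=True)
        X = balanced[feature_columns]
        y = balanced[label_column].to_numpy(dtype=int)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rseed)
        oof = np.zeros(len(y))
        for train_idx, test_idx in skf.split(X, y):
            cols = feature_columns
            if mrmr_k is not None and mrmr_k < len(feature_columns):
                # feature reduction inside the fold: held-out labels never
                # influence the selection
                cols = mrmr_select(X.iloc[train_idx], y[train_idx], mrmr_k)
            model = fit_classifier(
                X[cols].iloc[train_idx], y[train_idx], replace(params, seed=rseed)
            )
            oof[test_idx] = model.predict_proba(X[cols].iloc[test_idx])
        pred = (oof >= 0.5).astype(int)
        aucs.append(auc(oof, y))
        accs.append(float(np.mean(pred == y)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for cls in (0, 1):
                cm = class_metrics(pred, y, cls)
                pr[cls].append(cm.precision)
                se[cls].append(cm.sensitivity)
    per_class = {
        cls: ClassMetrics.from_precision_sensitivity(
            float(np.mean(pr[cls])), float(np.mean(se[cls]))
        )
        for cls in (0, 1)
    }
    return ModelEval(
        auc=float(np.mean(aucs)),
        accuracy=float(np.mean(accs)),
        per_class=per_class,
        n_repeats=n_repeats,
        seed=seed,
    )


def extract_importances(
    model: FittedClassifier | pd.Series, retention: float = 0.2
) -> pd.DataFrame:
    """Signed standardized coefficients, sorted by magnitude, with retention flags.

    Features are retained iff |coefficient| > ``retention``.  Accepts a
    fitted classifier or a raw coefficient Series (e.g. repeat-averaged).
    """
    if isinstance(model, FittedClassifier):
        coef = model.coefficients
    elif isinstance(model, pd.Series):
        coef = model.copy()
    else:
        raise ValueError("model must be a FittedClassifier (fitted) or coefficient Series")
    out = pd.DataFrame({"feature": coef.index, "coefficient": coef.to_numpy()})
    out["retained"] = out["coefficient"].abs() > retention
    out = out.reindex(out["coefficient"].abs().sort_values(ascending=False).index)
    out = out.reset_index(drop=True)
    if not out["retained"].any():
        warnings.warn(f"no coefficient exceeds the retention threshold {retention}")
    return out


def averaged_importances(
    table: pd.DataFrame,
    feature_columns: list[str],
    label_column: str,
    params: BoosterParams | None = None,
    n_repeats: int = 50,
    seed: int = 0,
    mrmr_k: int | None = 15,
    retention: float = 0.2,
) -> pd.DataFrame:
    """Coefficients averaged over repeated balanced fits, then thresholded.

    Features dropped by mRMR in a repeat contribute a zero coefficient for
    that repeat, so never-selected features cannot be retained.
    """
    params = params or BoosterParams()
    total = pd.Series(0.0, index=feature_columns)
    for r in range(n_repeats):
        rseed = seed + r
        balanced = downsample_balance(table, label_column, rseed).reset_index(drop=True)
        cols = feature_columns
        if mrmr_k is not None and mrmr_k < len(feature_columns):
            cols = mrmr_select(balanced[feature_columns], balanced[label_column], mrmr_k)
        model = fit_classifier(
            balanced[cols], balanced[label_column].to_numpy(dtype=int),
            replace(params, seed=rseed),
        )
        total.loc[cols] += model.coefficients
    return extract_importances(total / n_repeats, retention)
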