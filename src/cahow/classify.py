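"""Supervised behaviour classification from 15-s accelerometer segments.

The ethogram workflow: cut the per-sample metric table into non-overlapping
15-s segments, summarise each segment into 36 features (mean, IQR, 10th and
90th quantile of eight movement channels, plus mean surge, mean sway, mean
temperature and the wingbeat count), and train a random-forest classifier.
Training mirrors the caret/ranger recipe used in seabird ethogram studies:
classes are up-sampled to even sizes within training folds, hyperparameters
(minimum node size, variables per split, gini vs extremely-randomised
splits) are tuned by a random grid search under repeated stratified k-fold
cross-validation scored by Cohen's kappa, and recursive feature elimination
keeps the smallest feature subset whose kappa is within 1% of the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.utils import resample
from sklearn.utils.validation import check_is_fitted

from .taxonomy import collapse_modes

__all__ = [
    "segment",
    "featurize",
    "features_table",
    "cohens_kappa",
    "evaluate",
    "EvalReport",
    "BehaviourRandomForest",
    "ClassifierConfig",
    "train_classifier",
    "variable_importance",
]

# channels summarised by all four statistics
_STAT_CHANNELS = (
    "dyn_surge", "dyn_sway", "dyn_heave", "heave",
    "pitch", "roll", "vedba", "vesba",
)
_STATS = ("mean", "iqr", "q10", "q90")


def segment(metrics: pd.DataFrame, length: float = 15.0, rate: float = 25.0):
    """Cut a metric table into consecutive non-overlapping windows.

    ``metrics`` is a timestamp-indexed per-sample table (see
    :func:`cahow.signal_metrics.compute_metrics`).  Contiguous blocks are
    detected from the index spacing; windows never straddle a gap, and
    trailing partial windows are dropped.  Returns a list of DataFrames of
    exactly ``length * rate`` rows.
    """
    n_win = int(round(length * rate))
    if len(metrics) < n_win:
        raise ValueError("metric block shorter than one window")
    dt = np.diff(metrics.index.to_numpy()).astype("timedelta64[ns]").astype(float)
    gap = dt > 1.5e9 / rate
    block_ids = np.r_[0, np.cumsum(gap)]
    segments = []
    for _, block in metrics.groupby(block_ids):
        for k in range(len(block) // n_win):
            segments.append(block.iloc[k * n_win : (k + 1) * n_win])
    return segments


def featurize(seg: pd.DataFrame) -> dict[str, float]:
    """Summarise one 15-s segment into the 36 named predictor features."""
    missing = [c for c in (*_STAT_CHANNELS, "surge", "sway", "temp_c", "wingbeat")
               if c not in seg.columns]
    if missing:
        raise ValueError(f"segment is missing channels: {missing}")
    out: dict[str, float] = {}
    for ch in _STAT_CHANNELS:
        x = seg[ch].to_numpy(dtype=float)
        q10, q25, q75, q90 = np.quantile(x, [0.10, 0.25, 0.75, 0.90])
        out[f"{ch}_mean"] = float(np.mean(x))
        out[f"{ch}_iqr"] = float(q75 - q25)
        out[f"{ch}_q10"] = float(q10)
        out[f"{ch}_q90"] = float(q90)
    out["surge_mean"] = float(seg["surge"].mean())
    out["sway_mean"] = float(seg["sway"].mean())
    out["temp_mean"] = float(seg["temp_c"].mean())
    out["wingbeat_sum"] = float(seg["wingbeat"].sum())
    return out


FEATURE_NAMES = tuple(
    [f"{ch}_{st}" for ch in _STAT_CHANNELS for st in _STATS]
    + ["surge_mean", "sway_mean", "temp_mean", "wingbeat_sum"]
)


def features_table(segments, labels=None, bird=None) -> pd.DataFrame:
    """Feature vectors for a list of segments, one row each.

    Optionally attaches ``label`` and ``bird`` columns and the segment start
    time.
    """
    rows = []
    for i, seg in enumerate(segments):
        row = {"start": seg.index[0]}
        if bird is not None:
            row["bird"] = bird if np.isscalar(bird) else bird[i]
        row.update(featurize(seg))
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- evaluation

def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(np.r_[y_true, y_pred])
    n = len(y_true)
    po = np.mean(y_true == y_pred)
    pe = sum(
        np.mean(y_true == lab) * np.mean(y_pred == lab) for lab in labels
    )
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class EvalReport:
    """Confusion matrix plus overall and per-class performance metrics."""

    confusion: pd.DataFrame
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float
    per_class: pd.DataFrame  # precision, recall, balanced_accuracy per class

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "kappa": self.kappa,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def _clopper_pearson(k: int, n: int, alpha: float = 0.05):
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def evaluate(y_true, y_pred, labels=None) -> EvalReport:
    """Score predictions: accuracy with exact binomial (Clopper-Pearson) CI,
    Cohen's kappa, and per-class precision, recall and balanced accuracy
    (one-vs-rest)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if labels is None:
        labels = sorted(np.unique(np.r_[y_true, y_pred]).tolist())
    else:
        known = set(labels)
        stray = set(np.unique(np.r_[y_true, y_pred])) - known
        if stray:
            raise ValueError(f"labels outside taxonomy: {sorted(stray)}")
    n = len(y_true)
    cm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    correct = int(np.trace(cm.to_numpy()))
    acc = correct / n
    rows = {}
    for lab in labels:
        tp = cm.loc[lab, lab]
        fn = cm.loc[lab].sum() - tp
        fp = cm[lab].sum() - tp
        tn = n - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows[lab] = {
            "precision": prec,
            "recall": rec,
            "balanced_accuracy": np.nanmean([rec, spec]),
        }
    return EvalReport(
        confusion=cm,
        accuracy=acc,
        accuracy_ci=_clopper_pearson(correct, n),
        kappa=cohens_kappa(y_true, y_pred),
        per_class=pd.DataFrame(rows).T,
    )


# ----------------------------------------------------------------- training

def _upsample(X: pd.DataFrame, y: np.ndarray, seed: int):
    """Resample every class with replacement up to the largest class size."""
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    n_max = int(counts.max())
    parts_X, parts_y = [], []
    for j, lab in enumerate(counts.index):
        mask = y == lab
        Xl, yl = X[mask], y[mask]
        if mask.sum() < n_max:
            Xl, yl = resample(
                Xl, yl, replace=True, n_samples=n_max, random_state=seed + j
            )
        parts_X.append(Xl)
        parts_y.append(yl)
    return pd.concat(parts_X), np.concatenate(parts_y)


def _make_forest(rule: str, mtry: int, min_node: int, n_estimators: int, seed: int):
    cls = ExtraTreesClassifier if rule == "extratrees" else RandomForestClassifier
    return cls(
        n_estimators=n_estimators,
        max_features=mtry,
        min_samples_leaf=min_node,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


class BehaviourRandomForest(BaseEstimator, ClassifierMixin):
    """Random-forest ethogram classifier with tuning and feature selection.

    ``fit`` runs the full training recipe on the data it is given: random
    grid search over (min node size, variables per split, split rule) scored
    by repeated-CV kappa with within-fold up-sampling, then recursive
    feature elimination keeping the smallest subset within ``rfe_tol`` of
    the best kappa, then a final refit.  Prediction is by feature *name*, so
    it is invariant to column order.

    Defaults follow the published recipe (18-combination grid, 5x10 CV,
    1% RFE tolerance); smaller settings make desk-scale runs fast.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        grid_size: int = 18,
        cv_folds: int = 10,
        cv_repeats: int = 5,
        rfe_sizes: tuple = (4, 8, 12, 14, 18, 24, 30, 36),
        rfe_tol: float = 0.01,
        upsample: bool = True,
        min_node_range: tuple = (1, 10),
        split_rules: tuple = ("gini", "extratrees"),
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.grid_size = grid_size
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.rfe_sizes = rfe_sizes
        self.rfe_tol = rfe_tol
        self.upsample = upsample
        self.min_node_range = min_node_range
        self.split_rules = split_rules
        self.random_state = random_state

    def _cv_kappa(self, X, y, params, seed) -> float:
        cv = RepeatedStratifiedKFold(
            n_splits=self.cv_folds, n_repeats=self.cv_repeats, random_state=seed
        )
        scores = []
        for tr, te in cv.split(X, y):
            Xtr, ytr = X.iloc[tr], y[tr]
            if self.upsample:
                Xtr, ytr = _upsample(Xtr, ytr, seed)
            model = _make_forest(n_estimators=self.n_estimators, seed=seed, **params)
            model.fit(Xtr, ytr)
            scores.append(cohens_kappa(y[te], model.predict(X.iloc[te])))
        return float(np.mean(scores))

    def fit(self, X, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 behaviour classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 training instances")
        rng = np.random.default_rng(self.random_state)
        seed = int(rng.integers(0, 2**31 - 1))
        p = X.shape[1]
        # random grid over the declared hyperparameter ranges
        grid, seen = [], set()
        while len(grid) < self.grid_size:
            combo = (
                str(rng.choice(self.split_rules)),
                int(rng.integers(2, max(p, 3))),
                int(rng.integers(self.min_node_range[0], self.min_node_range[1] + 1)),
            )
            if combo in seen and len(seen) < 2 * p:  # avoid duplicate work
                continue
            seen.add(combo)
            grid.append({"rule": combo[0], "mtry": combo[1], "min_node": combo[2]})
        tuning = []
        for params in grid:
            tuning.append({**params, "cv_kappa": self._cv_kappa(X, y, params, seed)})
        self.cv_results_ = pd.DataFrame(tuning).sort_values(
            "cv_kappa", ascending=False, ignore_index=True
        )
        best = self.cv_results_.iloc[0]
        self.best_params_ = {
            "rule": best["rule"],
            "mtry": int(best["mtry"]),
            "min_node": int(best["min_node"]),
        }
        # RFE: rank features with the tuned model, evaluate nested subsets
        Xfull, yfull = (_upsample(X, y, seed) if self.upsample else (X, y))
        ranker = _make_forest(
            n_estimators=self.n_estimators, seed=seed, **self.best_params_
        )
        ranker.fit(Xfull, yfull)
        order = np.argsort(ranker.feature_importances_)[::-1]
        ranked = list(X.columns[order])
        sizes = sorted({min(s, p) for s in self.rfe_sizes})
        rfe_rows = []
        for s in sizes:
            cols = ranked[:s]
            params = dict(self.best_params_, mtry=min(self.best_params_["mtry"], s))
            rfe_rows.append(
                {"size": s, "cv_kappa": self._cv_kappa(X[cols], y, params, seed)}
            )
        self.rfe_results_ = pd.DataFrame(rfe_rows)
        best_kappa = self.rfe_results_["cv_kappa"].max()
        ok = self.rfe_results_[
            self.rfe_results_["cv_kappa"] >= best_kappa * (1 - self.rfe_tol)
        ]
        n_keep = int(ok["size"].min())
        self.selected_features_ = ranked[:n_keep]
        final_params = dict(
            self.best_params_, mtry=min(self.best_params_["mtry"], n_keep)
        )
        self.model_ = _make_forest(
            n_estimators=self.n_estimators, seed=seed, **final_params
        )
        self.model_.fit(Xfull[self.selected_features_], yfull)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = pd.DataFrame(X)
        return self.model_.predict(X[self.selected_features_])

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = pd.DataFrame(X)
        return self.model_.predict_proba(X[self.selected_features_])


@dataclass
class ClassifierConfig:
    """Training configuration (defaults follow the published recipe)."""

    split_fraction: float = 0.5
    cv_folds: int = 10
    cv_repeats: int = 5
    grid_size: int = 18
    rfe_sizes: tuple = (4, 8, 12, 14, 18, 24, 30, 36)
    rfe_tol: float = 0.01
    upsample: bool = True
    n_estimators: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainResult:
    model: BehaviourRandomForest
    report: EvalReport
    mode_report: EvalReport
    train_index: np.ndarray = field(repr=False, default=None)
    valid_index: np.ndarray = field(repr=False, default=None)


def train_classifier(features: pd.DataFrame, config: ClassifierConfig | None = None
                     ) -> TrainResult:
    """Train and validate the ethogram classifier on a labelled feature table.

    ``features`` must contain a ``label`` column plus feature columns (extra
    ``bird``/``start`` columns are ignored).  The data are split 50/50 (per
    ``split_fraction``) stratified by class; the model is tuned and fit on
    the training half, and evaluated on the withheld half at both the
    nine-class and the collapsed three-mode level.
    """
    config = config or ClassifierConfig()
    feat_cols = [
        c for c in features.columns if c not in ("label", "bird", "start")
    ]
    X = features[feat_cols]
    y = features["label"].to_numpy()
    idx = np.arange(len(features))
    tr, va = train_test_split(
        idx,
        train_size=config.split_fraction,
        stratify=y,
        random_state=config.seed,
    )
    clf = BehaviourRandomForest(
        n_estimators=config.n_estimators,
        grid_size=config.grid_size,
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
        rfe_sizes=config.rfe_sizes,
        rfe_tol=config.rfe_tol,
        upsample=config.upsample,
        random_state=config.seed,
    )
    clf.fit(X.iloc[tr], y[tr])
    y_hat = clf.predict(X.iloc[va])
    report = evaluate(y[va], y_hat)
    try:
        mode_report = evaluate(collapse_modes(y[va]), collapse_modes(y_hat))
    except ValueError:  # labels outside the nine-class ethogram
        mode_report = None
    return TrainResult(
        model=clf, report=report, mode_report=mode_report,
        train_index=tr, valid_index=va,
    )


def variable_importance(
    clf: BehaviourRandomForest, X, y, n_repeats: int = 5, random_state: int = 0
) -> pd.Series:
    """Permutation importance of the selected features, max-scaled to 100%."""
    check_is_fitted(clf, "model_")
    X = pd.DataFrame(X)[clf.selected_features_]
    res = permutation_importance(
        clf.model_, X, np.asarray(y), n_repeats=n_repeats,
        random_state=random_state, n_jobs=1,
    )
    imp = pd.Series(res.importances_mean, index=clf.selected_features_)
    imp = imp.clip(lower=0.0).sort_values(ascending=False)
    top = imp.max()
    return imp / top * 100.0 if top > 0 else imp
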