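"""Consensus feature selection and evaluation.

The engine repeats, over many random train/test splits, a two-stage feature
selection — an L1-penalized logistic regression scanned over a grid of
inverse-penalty strengths C (best C by stratified 5-fold cross-validated
AUC-ROC), followed by recursive feature elimination down to k features —
then evaluates a near-unpenalized logistic model of the selected features
on the held-out split.  Splits are constrained so the rare class (NDR) is
divided into fixed train/test case counts (10/4 for the 234-sample cohort).
Selected feature combinations are tallied across trials; the modal
combination is the reported signature, and a representative trial (metric
vector closest to the mean in SD units) provides the reported ROC/PRC
curves.

Conventions: C is the inverse regularization strength (larger C = weaker
L1 penalty); AUC-ROC uses midrank tie handling; AUC-PRC is the stepwise
(average-precision) interpolation; the classification cutoff maximizes
Youden's J = sensitivity + specificity over the unique score thresholds of
the designated curve (test scores by default), ties resolved toward the
lower cutoff (higher sensitivity).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seed, rng_for
from .containers import labels_to_binary
from .errors import ConfigError, DataError
from .features import FeatureMatrix, standardize

__all__ = [
    "TrialConfig",
    "TrialResult",
    "ConsensusReport",
    "constrained_split",
    "lasso_stage",
    "rfe_stage",
    "evaluate",
    "run_trials",
    "compare_trial_sets",
    "ConsensusLassoRFE",
]

_RFE_C = 1e6  # effectively unpenalized refit for importance ranking


@dataclass
class TrialConfig:
    n_trials: int = 100
    test_fraction: float = 0.2
    case_split: tuple[int, int] = (10, 4)
    c_grid: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    cv_folds: int = 5
    k_features: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.k_features < 1 or self.cv_folds < 2:
            raise ConfigError("n_trials, k_features, cv_folds out of range")
        if not (0 < self.test_fraction < 1):
            raise ConfigError("test_fraction in (0,1)")
        grid = list(self.c_grid)
        if not grid or any(c <= 0 for c in grid) or grid != sorted(grid):
            raise ConfigError("c_grid must be positive and ascending")


@dataclass
class TrialResult:
    trial: int
    selected: tuple[str, ...]  # sorted feature names
    best_c: float
    cv_auc_roc: float
    test_auc_roc: float
    test_auc_prc: float
    cutoff: float
    sensitivity: float
    specificity: float
    precision: float
    notes: list[str] = field(default_factory=list)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity

    def metric_vector(self) -> np.ndarray:
        return np.array([self.test_auc_roc, self.test_auc_prc, self.sensitivity, self.specificity, self.precision])


_METRICS = ["cv_auc_roc", "test_auc_roc", "test_auc_prc", "sensitivity", "specificity", "precision", "youden_j"]


@dataclass
class ConsensusReport:
    combination_freq: dict[tuple[str, ...], int]
    single_feature_freq: dict[str, int]
    metric_means: dict[str, float]
    metric_sds: dict[str, float]  # population SD
    representative: int
    n_trials: int

    @property
    def modal_combination(self) -> tuple[str, ...]:
        return max(self.combination_freq, key=lambda k: (self.combination_freq[k], k))

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "combination_freq": {"|".join(k): v for k, v in sorted(self.combination_freq.items(), key=lambda kv: (-kv[1], kv[0]))},
            "single_feature_freq": dict(sorted(self.single_feature_freq.items(), key=lambda kv: (-kv[1], kv[0]))),
            "metric_means": self.metric_means,
            "metric_sds": self.metric_sds,
            "representative": self.representative,
        }


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def constrained_split(labels: pd.Series, cfg: TrialConfig, trial_seed: int) -> tuple[list[str], list[str]]:
    """Case-constrained random train/test split.

    Exactly ``case_split`` cases land in train/test; controls fill the test
    set to round(n * test_fraction) (half away from zero).  Deterministic
    under ``trial_seed``; train and test are disjoint and exhaustive.
    """
    y = labels_to_binary(labels)
    ids = np.asarray(labels.index)
    cases = ids[y.to_numpy() == 1]
    controls = ids[y.to_numpy() == 0]
    tr_cases, te_cases = cfg.case_split
    if len(cases) != tr_cases + te_cases:
        raise DataError(f"case_split {cfg.case_split} requires {tr_cases + te_cases} cases, found {len(cases)}")
    n_test = _round_half_away(len(ids) * cfg.test_fraction)
    te_controls = n_test - te_cases
    if te_controls < 0 or te_controls > len(controls):
        raise DataError("test size incompatible with case_split")
    rng = rng_for(trial_seed, "split")
    case_perm = rng.permutation(len(cases))
    control_perm = rng.permutation(len(controls))
    test_ids = set(cases[case_perm[:te_cases]]) | set(controls[control_perm[:te_controls]])
    test = [s for s in ids if s in test_ids]
    train = [s for s in ids if s not in test_ids]
    return train, test


def _cv_auc(X: np.ndarray, y: np.ndarray, c: float, folds: StratifiedKFold, splits) -> float:
    aucs = []
    for tr, te in splits:
        model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear", tol=1e-6, max_iter=10_000, random_state=0)
        model.fit(X[tr], y[tr])
        scores = model.decision_function(X[te])
        aucs.append(roc_auc_score(y[te], scores))
    return float(np.mean(aucs))


def lasso_stage(
    X: pd.DataFrame, y: pd.Series, cfg: TrialConfig, trial_seed: int
) -> tuple[list[str], float, float, list[str]]:
    """C-grid scan of L1 logistic regression scored by stratified CV AUC-ROC.

    Returns (surviving features, best C, its CV AUC, tie notes).  Survivors
    are the features with nonzero coefficient in the full-training-split fit
    at the best C (ties toward the smallest C).
    """
    yv = labels_to_binary(y).to_numpy()
    if yv.sum() < cfg.cv_folds or (1 - yv).sum() < cfg.cv_folds:
        raise DataError(f"stratified {cfg.cv_folds}-fold CV impossible: class counts {yv.sum()}/{(1 - yv).sum()}")
    Xv = X.to_numpy(dtype=float)
    folds = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=child_seed(trial_seed, "cv"))
    splits = list(folds.split(Xv, yv))
    best_c, best_auc = None, -np.inf
    notes = []
    for c in cfg.c_grid:
        auc = _cv_auc(Xv, yv, c, folds, splits)
        if auc > best_auc:
            best_c, best_auc = c, auc
        elif auc == best_auc:
            notes.append(f"cv-auc tie at C={c} (kept C={best_c})")
    model = LogisticRegression(l1_ratio=1.0, C=best_c, solver="liblinear", tol=1e-6, max_iter=10_000, random_state=0)
    model.fit(Xv, yv)
    survivors = [f for f, w in zip(X.columns, model.coef_.ravel()) if w != 0.0]
    if not survivors:
        raise DataError(f"no feature survived the L1 stage at C={best_c}")
    return survivors, float(best_c), float(best_auc), notes


def rfe_stage(X: pd.DataFrame, y: pd.Series, k: int) -> tuple[list[str], list[str]]:
    """Recursive feature elimination by refit |coefficient| importance.

    Repeatedly fits a near-unpenalized (L2, C=1e6) logistic model and drops
    the feature with the smallest absolute coefficient (tie: the
    lexicographically last name) until k features remain; returns the
    selection sorted by name plus tie notes.  If fewer than k features are
    supplied, all are returned with a warning.
    """
    yv = labels_to_binary(y).to_numpy()
    cols = list(X.columns)
    notes = []
    if len(cols) < k:
        warnings.warn(f"RFE asked for {k} features but only {len(cols)} survive; returning all", stacklevel=2)
        return sorted(cols), [f"survivors {len(cols)} < k {k}"]
    while len(cols) > k:
        model = LogisticRegression(l1_ratio=0.0, C=_RFE_C, solver="liblinear", tol=1e-6, max_iter=10_000, random_state=0)
        model.fit(X[cols].to_numpy(dtype=float), yv)
        imp = np.abs(model.coef_.ravel())
        low = imp.min()
        tied = [c for c, v in zip(cols, imp) if v == low]
        drop = max(tied)
        if len(tied) > 1:
            notes.append(f"importance tie among {sorted(tied)}; dropped {drop}")
        cols.remove(drop)
    return sorted(cols), notes


def youden_cutoff(scores: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity over unique scores.

    A sample is called positive when its score >= cutoff.  On a tie in J,
    the lowest cutoff (highest sensitivity) wins.  Returns (cutoff,
    sensitivity, specificity).
    """
    uniq = np.unique(scores)  # ascending; iterate low->high, strict improvement keeps the lowest
    pos = y == 1
    best = None
    for thr in uniq:
        pred = scores >= thr
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        if best is None or sens + spec > best[3]:
            best = (float(thr), float(sens), float(spec), sens + spec)
    return best[0], best[1], best[2]


def evaluate(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    selected: list[str],
    cutoff_from: str = "test",
) -> dict:
    """Fit a logistic model of the selected features; score the test split.

    Returns test AUC-ROC (midrank), AUC-PRC (stepwise), and cutoff metrics.
    ``cutoff_from="train"`` derives the Youden cutoff from training scores
    (the methodologically conservative option) instead of the test curve.
    """
    if cutoff_from not in {"test", "train"}:
        raise ConfigError(f"unknown cutoff_from {cutoff_from!r}")
    ytr = labels_to_binary(y_train).to_numpy()
    yte = labels_to_binary(y_test).to_numpy()
    if yte.sum() == 0 or yte.sum() == len(yte):
        raise DataError("degenerate test split: one class only")
    model = LogisticRegression(l1_ratio=0.0, C=_RFE_C, solver="liblinear", tol=1e-6, max_iter=10_000, random_state=0)
    model.fit(X_train[selected].to_numpy(dtype=float), ytr)
    test_scores = model.predict_proba(X_test[selected].to_numpy(dtype=float))[:, 1]
    auc_roc = float(roc_auc_score(yte, test_scores))
    auc_prc = float(average_precision_score(yte, test_scores))
    if cutoff_from == "test":
        cutoff, _, _ = youden_cutoff(test_scores, yte)
    else:
        train_scores = model.predict_proba(X_train[selected].to_numpy(dtype=float))[:, 1]
        cutoff, _, _ = youden_cutoff(train_scores, ytr)
    pred = test_scores >= cutoff
    sens = float((pred & (yte == 1)).sum() / (yte == 1).sum())
    spec = float((~pred & (yte == 0)).sum() / (yte == 0).sum())
    prec = float((pred & (yte == 1)).sum() / pred.sum()) if pred.any() else 0.0
    return {
        "model": model,
        "test_scores": test_scores,
        "test_auc_roc": auc_roc,
        "test_auc_prc": auc_prc,
        "cutoff": float(cutoff),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
    }


def _representative(trials: list[TrialResult]) -> int:
    mat = np.array([t.metric_vector() for t in trials])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return 0
    z = (mat[:, keep] - mean[keep]) / sd[keep]
    return int(np.argmin(np.linalg.norm(z, axis=1)))


def run_trials(
    fm: FeatureMatrix,
    labels: pd.Series,
    cfg: TrialConfig,
    scaling: str = "per-split",
    cutoff_from: str = "test",
) -> tuple[ConsensusReport, list[TrialResult]]:
    """The full consensus procedure: n_trials independent split/select/evaluate runs.

    ``scaling="per-split"`` fits the standardizer on each trial's training
    split (no leakage); ``"global"`` standardizes once on the full cohort
    before splitting.  Trial t uses trial_seed = base_seed + t, so the whole
    report is reproducible from base_seed alone.
    """
    if scaling not in {"per-split", "global"}:
        raise ConfigError(f"unknown scaling mode {scaling!r}")
    labels = labels.loc[fm.data.index]
    if scaling == "global":
        fm_global, _ = standardize(fm)
    trials: list[TrialResult] = []
    for t in range(cfg.n_trials):
        trial_seed = cfg.base_seed + t
        try:
            train_ids, test_ids = constrained_split(labels, cfg, trial_seed)
            if scaling == "per-split":
                fm_t, _ = standardize(fm, fit_on=train_ids)
            else:
                fm_t = fm_global
            Xtr, Xte = fm_t.data.loc[train_ids], fm_t.data.loc[test_ids]
            ytr, yte = labels.loc[train_ids], labels.loc[test_ids]
            survivors, best_c, cv_auc, notes1 = lasso_stage(Xtr, ytr, cfg, trial_seed)
            selected, notes2 = rfe_stage(Xtr[survivors], ytr, cfg.k_features)
            ev = evaluate(Xtr, ytr, Xte, yte, selected, cutoff_from=cutoff_from)
        except Exception as exc:
            raise DataError(f"trial {t} failed: {exc}") from exc
        trials.append(
            TrialResult(
                trial=t,
                selected=tuple(selected),
                best_c=best_c,
                cv_auc_roc=cv_auc,
                test_auc_roc=ev["test_auc_roc"],
                test_auc_prc=ev["test_auc_prc"],
                cutoff=ev["cutoff"],
                sensitivity=ev["sensitivity"],
                specificity=ev["specificity"],
                precision=ev["precision"],
                notes=notes1 + notes2,
            )
        )
    combo = Counter(t.selected for t in trials)
    single = Counter(f for t in trials for f in t.selected)
    means = {m: float(np.mean([getattr(t, m) for t in trials])) for m in _METRICS}
    sds = {m: float(np.std([getattr(t, m) for t in trials])) for m in _METRICS}
    report = ConsensusReport(
        combination_freq=dict(combo),
        single_feature_freq=dict(single),
        metric_means=means,
        metric_sds=sds,
        representative=_representative(trials),
        n_trials=cfg.n_trials,
    )
    return report, trials


def rerun_trial(
    fm: FeatureMatrix,
    labels: pd.Series,
    cfg: TrialConfig,
    trial_index: int,
    scaling: str = "per-split",
    cutoff_from: str = "test",
) -> dict:
    """Re-execute one trial deterministically; returns its evaluate() dict
    plus the test labels (for ROC/PRC point extraction)."""
    labels = labels.loc[fm.data.index]
    trial_seed = cfg.base_seed + trial_index
    train_ids, test_ids = constrained_split(labels, cfg, trial_seed)
    fm_t, _ = standardize(fm, fit_on=train_ids if scaling == "per-split" else None)
    Xtr, Xte = fm_t.data.loc[train_ids], fm_t.data.loc[test_ids]
    ytr, yte = labels.loc[train_ids], labels.loc[test_ids]
    survivors, _, _, _ = lasso_stage(Xtr, ytr, cfg, trial_seed)
    selected, _ = rfe_stage(Xtr[survivors], ytr, cfg.k_features)
    ev = evaluate(Xtr, ytr, Xte, yte, selected, cutoff_from=cutoff_from)
    ev["y_test"] = labels_to_binary(yte).to_numpy()
    ev["selected"] = selected
    return ev


def compare_trial_sets(aucs_a, aucs_b) -> tuple[float, float]:
    """Two-sided pooled-variance t-test between two AUC distributions."""
    a, b = np.asarray(aucs_a, dtype=float), np.asarray(aucs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DataError("zero variance in both lists with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


class ConsensusLassoRFE:
    """Classifier-style wrapper around the consensus selection engine.

    fit(X, y) runs the repeated-split LASSO+RFE procedure on a feature
    DataFrame (all columns treated as numeric unless a FeatureMatrix is
    given), stores ``consensus_report_``, ``trials_`` and the modal
    combination ``selected_features_``, then refits a near-unpenalized
    logistic model of the modal features on the full (globally
    standardized) data for predict/predict_proba.
    """

    def __init__(
        self,
        n_trials: int = 100,
        test_fraction: float = 0.2,
        case_split: tuple[int, int] = (10, 4),
        c_grid: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
        cv_folds: int = 5,
        k_features: int = 1,
        base_seed: int = 0,
        scaling: str = "per-split",
        cutoff_from: str = "test",
    ):
        self.n_trials = n_trials
        self.test_fraction = test_fraction
        self.case_split = case_split
        self.c_grid = c_grid
        self.cv_folds = cv_folds
        self.k_features = k_features
        self.base_seed = base_seed
        self.scaling = scaling
        self.cutoff_from = cutoff_from

    _PARAMS = [
        "n_trials", "test_fraction", "case_split", "c_grid", "cv_folds",
        "k_features", "base_seed", "scaling", "cutoff_from",
    ]

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAMS}

    def set_params(self, **params) -> "ConsensusLassoRFE":
        for k, v in params.items():
            if k not in self._PARAMS:
                raise ConfigError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> TrialConfig:
        return TrialConfig(
            n_trials=self.n_trials,
            test_fraction=self.test_fraction,
            case_split=tuple(self.case_split),
            c_grid=tuple(self.c_grid),
            cv_folds=self.cv_folds,
            k_features=self.k_features,
            base_seed=self.base_seed,
        )

    def fit(self, X, y) -> "ConsensusLassoRFE":
        if isinstance(X, FeatureMatrix):
            fm = X
        else:
            X = pd.DataFrame(X)
            fm = FeatureMatrix(X, {c: "gene" for c in X.columns}, {c: "numeric" for c in X.columns})
        y = pd.Series(y, index=fm.data.index) if not isinstance(y, pd.Series) else y
        self.consensus_report_, self.trials_ = run_trials(fm, y, self._config(), scaling=self.scaling, cutoff_from=self.cutoff_from)
        self.selected_features_ = list(self.consensus_report_.modal_combination)
        fm_std, self.scaler_ = standardize(fm)
        yv = labels_to_binary(y.loc[fm.data.index]).to_numpy()
        self.classes_ = np.array([0, 1])
        self.final_model_ = LogisticRegression(l1_ratio=0.0, C=_RFE_C, solver="liblinear", tol=1e-6, max_iter=10_000, random_state=0)
        self.final_model_.fit(fm_std.data[self.selected_features_].to_numpy(dtype=float), yv)
        self._columns = list(fm.data.columns)
        return self

    def _prepare(self, X) -> np.ndarray:
        df = X.data if isinstance(X, FeatureMatrix) else pd.DataFrame(X, columns=self._columns)
        scaled = df.drop(columns=self.scaler_.dropped_, errors="ignore").copy()
        std = self.scaler_.transform(df)
        scaled[std.columns] = std
        return scaled[self.selected_features_].to_numpy(dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        return self.final_model_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.final_model_.predict(self._prepare(X))

    def score(self, X, y) -> float:
        yv = labels_to_binary(pd.Series(y)).to_numpy()
        return float(roc_auc_score(yv, self.predict_proba(X)[:, 1]))
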