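"""Consensus selection engine: splits, stages, metrics, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from tira.containers import labels_to_binary
from tira.errors import ConfigError, DataError
from tira.features import FeatureMatrix
from tira.select_train import (
    ConsensusLassoRFE,
    TrialConfig,
    compare_trial_sets,
    constrained_split,
    evaluate,
    lasso_stage,
    rfe_stage,
    run_trials,
    youden_cutoff,
)

from ._oracles import auc_pairs


def _labels(n, cases, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, cases, replace=False)] = 1
    return pd.Series(np.where(y == 1, "NDR", "DR"), index=[f"s{i}" for i in range(n)])


def _fm(X, index=None):
    df = pd.DataFrame(X, index=index, columns=[f"f{j:03d}" for j in range(np.shape(X)[1])])
    return FeatureMatrix(df, {c: "gene" for c in df.columns}, {c: "numeric" for c in df.columns})


# ----------------------------------------------------------------- splits


def test_constrained_split_study_geometry():
    labels = _labels(234, 14)
    cfg = TrialConfig()
    train, test = constrained_split(labels, cfg, trial_seed=1)
    y = labels_to_binary(labels)
    assert len(test) == 47 and len(train) == 187
    assert y[test].sum() == 4 and y[train].sum() == 10
    assert set(train) | set(test) == set(labels.index)
    assert set(train).isdisjoint(test)


def test_split_deterministic_and_seed_sensitive():
    labels = _labels(234, 14)
    cfg = TrialConfig()
    a1 = constrained_split(labels, cfg, 5)
    a2 = constrained_split(labels, cfg, 5)
    b = constrained_split(labels, cfg, 6)
    assert a1 == a2
    assert a1 != b
    # case counts identical across seeds
    y = labels_to_binary(labels)
    assert y[b[1]].sum() == 4


def test_split_rounding_small_cohort():
    labels = _labels(10, 2)
    cfg = TrialConfig(case_split=(1, 1))
    train, test = constrained_split(labels, cfg, 0)
    assert len(test) == 2  # round(10*0.2)
    y = labels_to_binary(labels)
    assert y[test].sum() == 1


def test_split_rejects_wrong_case_count():
    labels = _labels(50, 5)
    with pytest.raises(DataError):
        constrained_split(labels, TrialConfig(case_split=(10, 4)), 0)


# ----------------------------------------------------------------- stages


def test_lasso_keeps_separating_feature():
    rng = np.random.default_rng(2)
    n = 100
    y = _labels(n, 20, seed=2)
    yv = labels_to_binary(y).to_numpy()
    X = rng.normal(size=(n, 5))
    X[:, 3] = yv * 2.0 + rng.normal(scale=0.05, size=n)  # near-separating
    X = (X - X.mean(0)) / X.std(0)
    survivors, best_c, cv_auc, _ = lasso_stage(pd.DataFrame(X, index=y.index, columns=list("abcde")), y, TrialConfig(), 0)
    assert "d" in survivors
    assert cv_auc > 0.9


def test_lasso_null_features_cv_auc_near_half():
    aucs = []
    for rep in range(5):
        rng = np.random.default_rng(100 + rep)
        y = _labels(120, 24, seed=rep)
        X = rng.normal(size=(120, 10))
        _, _, cv_auc, _ = lasso_stage(pd.DataFrame(X, index=y.index, columns=[f"f{j}" for j in range(10)]), y, TrialConfig(), rep)
        aucs.append(cv_auc)
    assert abs(np.mean(aucs) - 0.5) < 0.12


def test_rfe_identity_when_k_equals_survivors():
    rng = np.random.default_rng(3)
    y = _labels(60, 12, seed=3)
    X = pd.DataFrame(rng.normal(size=(60, 4)), index=y.index, columns=list("dcba"))
    selected, _ = rfe_stage(X, y, k=4)
    assert selected == ["a", "b", "c", "d"]  # sorted by name


def test_rfe_warns_when_too_few_survivors():
    rng = np.random.default_rng(4)
    y = _labels(40, 8, seed=4)
    X = pd.DataFrame(rng.normal(size=(40, 2)), index=y.index, columns=list("ab"))
    with pytest.warns(UserWarning):
        selected, notes = rfe_stage(X, y, k=5)
    assert selected == ["a", "b"] and notes


def test_rfe_recovers_planted_feature():
    hits = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(200 + rep)
        y = _labels(234, 14, seed=rep)
        yv = labels_to_binary(y).to_numpy()
        X = rng.normal(size=(234, 10))
        X[:, 0] += 2.0 * yv  # planted effect, 2 SD
        X = (X - X.mean(0)) / X.std(0)
        df = pd.DataFrame(X, index=y.index, columns=[f"f{j}" for j in range(10)])
        selected, _ = rfe_stage(df, y, k=1)
        hits += selected == ["f0"]
    assert hits >= 0.9 * reps


def test_rfe_deterministic():
    rng = np.random.default_rng(5)
    y = _labels(80, 10, seed=5)
    X = pd.DataFrame(rng.normal(size=(80, 6)), index=y.index, columns=[f"f{j}" for j in range(6)])
    assert rfe_stage(X, y, 2) == rfe_stage(X, y, 2)


# ---------------------------------------------------------------- metrics


def test_auc_pair_counting_example():
    scores = np.array([0.9, 0.8, 0.7, 0.6])
    labels = np.array([1, 0, 1, 0])
    assert roc_auc_score(labels, scores) == pytest.approx(0.75)
    assert auc_pairs(scores, labels) == pytest.approx(0.75)


def test_auc_matches_pair_oracle_with_ties():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n = rng.integers(4, 31)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        assert roc_auc_score(y, scores) == pytest.approx(auc_pairs(scores, y), abs=1e-12)


def test_youden_perfect_separation():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    y = np.array([1, 1, 0, 0])
    cutoff, sens, spec = youden_cutoff(scores, y)
    assert sens == 1.0 and spec == 1.0
    assert 0.2 < cutoff <= 0.8


def test_youden_tie_takes_lower_cutoff():
    # two cutoffs reach the same J; brute force confirms the tie, rule picks lower
    scores = np.array([0.9, 0.7, 0.5, 0.3])
    y = np.array([1, 0, 1, 0])
    js = {}
    for thr in np.unique(scores):
        pred = scores >= thr
        js[thr] = (pred & (y == 1)).sum() / 2 + (~pred & (y == 0)).sum() / 2
    best = max(js.values())
    tied = sorted(t for t, j in js.items() if j == best)
    assert len(tied) > 1  # genuine tie in this construction
    cutoff, _, _ = youden_cutoff(scores, y)
    assert cutoff == pytest.approx(tied[0])


def test_evaluate_perfect_model():
    rng = np.random.default_rng(7)
    yv = np.array([1 if i % 6 == 0 else 0 for i in range(60)])
    y = pd.Series(np.where(yv == 1, "NDR", "DR"), index=[f"s{i}" for i in range(60)])
    X = pd.DataFrame({"f0": yv * 4.0 + rng.normal(scale=0.01, size=60)}, index=y.index)
    train_ids, test_ids = list(y.index[:40]), list(y.index[40:])
    ev = evaluate(X.loc[train_ids], y[train_ids], X.loc[test_ids], y[test_ids], ["f0"])
    assert ev["test_auc_roc"] == 1.0
    assert ev["test_auc_prc"] == 1.0
    assert ev["sensitivity"] + ev["specificity"] == 2.0


# ------------------------------------------------------------- run_trials


@pytest.fixture(scope="module")
def planted_run():
    rng = np.random.default_rng(8)
    y = _labels(234, 14, seed=8)
    yv = labels_to_binary(y).to_numpy()
    X = rng.normal(size=(234, 12))
    X[:, 5] += 2.2 * yv
    fm = _fm(X, index=y.index)
    cfg = TrialConfig(n_trials=12, base_seed=3)
    report, trials = run_trials(fm, y, cfg)
    return fm, y, cfg, report, trials


def test_frequencies_conserved(planted_run):
    _, _, cfg, report, trials = planted_run
    assert sum(report.combination_freq.values()) == cfg.n_trials
    assert len(trials) == cfg.n_trials
    assert all(len(t.selected) == cfg.k_features for t in trials)


def test_planted_feature_modal(planted_run):
    *_, report, _ = planted_run
    assert report.modal_combination == ("f005",)


def test_report_bit_reproducible(planted_run):
    fm, y, cfg, report, _ = planted_run
    report2, _ = run_trials(fm, y, cfg)
    assert report.to_dict() == report2.to_dict()


def test_combination_freq_invariant_to_column_order(planted_run):
    fm, y, cfg, report, _ = planted_run
    cols = list(fm.data.columns)[::-1]
    fm_rev = FeatureMatrix(fm.data[cols], fm.provenance, fm.encoding)
    report2, _ = run_trials(fm_rev, y, cfg)
    assert report.combination_freq == report2.combination_freq


def test_zeroed_clinical_features_do_not_change_selection(planted_run):
    fm, y, cfg, report, _ = planted_run
    data = fm.data.copy()
    data["clin_a"] = 0.0  # constant: dropped by the per-split standardizer
    data["clin_b"] = 0.0
    prov = dict(fm.provenance, clin_a="clinical", clin_b="clinical")
    enc = dict(fm.encoding, clin_a="numeric", clin_b="numeric")
    with pytest.warns(UserWarning):
        report2, _ = run_trials(FeatureMatrix(data, prov, enc), y, cfg)
    assert report.combination_freq == report2.combination_freq


def test_representative_trial_in_range(planted_run):
    _, _, cfg, report, trials = planted_run
    assert 0 <= report.representative < cfg.n_trials
    # representative minimizes SD-scaled distance to the metric means
    mat = np.array([t.metric_vector() for t in trials])
    mean, sd = mat.mean(0), mat.std(0)
    keep = sd > 0
    dists = np.linalg.norm((mat[:, keep] - mean[keep]) / sd[keep], axis=1)
    assert dists[report.representative] == pytest.approx(dists.min())


# --------------------------------------------------------- trial-set t-test


def test_compare_identical_lists():
    t, p = compare_trial_sets([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
    assert t == 0.0 and p == 1.0


def test_compare_separated_lists():
    rng = np.random.default_rng(9)
    a = 0.9 + rng.normal(scale=1e-3, size=50)
    b = 0.7 + rng.normal(scale=1e-3, size=50)
    t, p = compare_trial_sets(a, b)
    assert p < 1e-10 and t > 0


def test_compare_swap_negates_t():
    a, b = [0.9, 0.85, 0.8], [0.7, 0.72, 0.71]
    t1, p1 = compare_trial_sets(a, b)
    t2, p2 = compare_trial_sets(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


# ---------------------------------------------------------- estimator API


def test_consensus_estimator_sklearn_surface():
    from sklearn.base import clone

    rng = np.random.default_rng(10)
    y = _labels(100, 10, seed=10)
    yv = labels_to_binary(y).to_numpy()
    X = rng.normal(size=(100, 6))
    X[:, 2] += 2.5 * yv
    df = pd.DataFrame(X, index=y.index, columns=[f"g{j}" for j in range(6)])
    est = ConsensusLassoRFE(n_trials=5, case_split=(8, 2), base_seed=1)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    est.fit(df, y)
    assert est.selected_features_ == ["g2"]
    proba = est.predict_proba(df)
    assert proba.shape == (100, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert est.score(df, y) > 0.8
    with pytest.raises(ConfigError):
        est.set_params(nope=1)
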