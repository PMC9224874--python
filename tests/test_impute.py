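"""Expression imputation: harmonization, linearity, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from tira.containers import GenotypeMatrix, WeightDB
from tira.errors import DataError
from tira.features import FeatureMatrix, standardize
from tira.impute import ExpressionImputer, harmonize, impute
from tira import io
from tira.synth import SynthConfig, simulate_cohort


def _gm(arr, ref="A", alt="G"):
    arr = np.asarray(arr, dtype=float)
    vids = [f"v{j}" for j in range(arr.shape[1])]
    variants = pd.DataFrame(
        {"chrom": 1, "pos": np.arange(arr.shape[1]) + 1, "ref": ref, "alt": alt},
        index=pd.Index(vids, name="id"),
    )
    return GenotypeMatrix(pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=vids), variants)


def _db(rows):
    return WeightDB(pd.DataFrame(rows, columns=["gene", "variant_id", "effect_allele", "non_effect_allele", "weight"]))


# ------------------------------------------------------------ harmonization


@pytest.mark.parametrize(
    "ref,alt,eff,non,expected",
    [
        ("A", "G", "G", "A", "identity"),
        ("G", "A", "G", "A", "flip"),
        ("A", "G", "C", "T", "skip"),
        ("A", "G", "C", "A", "skip"),
    ],
)
def test_harmonize_actions(ref, alt, eff, non, expected):
    variant = pd.Series({"ref": ref, "alt": alt})
    w = pd.Series({"effect_allele": eff, "non_effect_allele": non})
    action, reason = harmonize(variant, w)
    assert action == expected
    if expected == "skip":
        assert reason == "allele mismatch"


def test_harmonize_ambiguous_policy():
    variant = pd.Series({"ref": "A", "alt": "T"})
    w = pd.Series({"effect_allele": "T", "non_effect_allele": "A"})
    assert harmonize(variant, w)[0] == "identity"  # default: exact match accepted
    assert harmonize(variant, w, ambiguous="drop") == ("skip", "strand ambiguous")


# ------------------------------------------------------------- arithmetic


def test_scalar_product():
    g = _gm([[2.0, 1.0]])
    db = _db([("g1", "v0", "G", "A", 0.5), ("g1", "v1", "G", "A", -0.25)])
    em = impute(g, db)
    assert em.values.loc["s0", "g1"] == pytest.approx(0.75)


def test_zero_weights_give_zero_expression():
    g = _gm(np.random.default_rng(0).integers(0, 3, size=(5, 2)))
    db = _db([("g1", "v0", "G", "A", 0.0), ("g1", "v1", "G", "A", 0.0)])
    em = impute(g, db)
    assert (em.values["g1"] == 0).all()


def test_duplicate_weight_rows_error():
    with pytest.raises(DataError, match="g1.*v0|duplicate"):
        _db([("g1", "v0", "G", "A", 0.5), ("g1", "v0", "G", "A", 0.2)])


def test_no_overlap_is_hard_error():
    g = _gm([[1.0]])
    db = _db([("g1", "nope", "G", "A", 0.5)])
    with pytest.raises(DataError, match="no overlap"):
        impute(g, db)


def test_missing_model_variant_lowers_coverage():
    g = _gm([[1.0, 2.0]])
    db = _db([("g1", "v0", "G", "A", 0.5), ("g1", "zzz", "G", "A", 1.0)])
    em = impute(g, db)
    assert em.coverage["g1"] == pytest.approx(0.5)


# --------------------------------------------------------- flip invariance


def test_allele_swap_with_negated_weight_shifts_by_constant():
    # (effect=alt, w) and (effect=ref, -w) are the same model up to +2w;
    # standardized features must be bit-identical.
    rng = np.random.default_rng(1)
    g = _gm(rng.integers(0, 3, size=(30, 3)))
    db = _db([("g1", "v0", "G", "A", 0.5), ("g1", "v1", "G", "A", -0.3), ("g1", "v2", "G", "A", 0.8)])
    db_swapped = _db([("g1", "v0", "A", "G", -0.5), ("g1", "v1", "G", "A", -0.3), ("g1", "v2", "G", "A", 0.8)])
    em = impute(g, db)
    em2 = impute(g, db_swapped)
    diff = em2.values["g1"] - em.values["g1"]
    # swapped record contributes -w*(2-d) = -2w + w*d: same slope, constant -2w
    assert np.allclose(diff, -2 * 0.5)
    fm1 = FeatureMatrix(em.values, {"g1": "gene"}, {"g1": "numeric"})
    fm2 = FeatureMatrix(em2.values, {"g1": "gene"}, {"g1": "numeric"})
    s1, _ = standardize(fm1)
    s2, _ = standardize(fm2)
    assert np.allclose(s1.data.to_numpy(), s2.data.to_numpy(), atol=1e-12)


def test_true_allele_swap_recoded_dosages_identical():
    # swapping ref/alt AND recoding d -> 2-d in the genotype file is a pure
    # representation change; harmonization must restore identical output
    rng = np.random.default_rng(2)
    arr = rng.integers(0, 3, size=(20, 2)).astype(float)
    g = _gm(arr)
    swapped = _gm(2.0 - arr, ref="G", alt="A")
    db = _db([("g1", "v0", "G", "A", 0.5), ("g1", "v1", "G", "A", -0.25)])
    em, em2 = impute(g, db), impute(swapped, db)
    pd.testing.assert_frame_equal(em.values, em2.values)


# ---------------------------------------------------- linearity properties


def test_doubling_weights_doubles_values(tiny_cohort):
    _, g, db, *_ = tiny_cohort
    doubled = WeightDB(db.weights.assign(weight=db.weights["weight"] * 2), tissue=db.tissue)
    em = impute(g, db, missing="skip")
    em2 = impute(g, doubled, missing="skip")
    assert np.allclose(em2.values.to_numpy(), 2 * em.values.to_numpy())


def test_concat_equals_separate_with_frozen_means(tiny_cohort):
    _, g, db, *_ = tiny_cohort
    imp = ExpressionImputer(db).fit(g)
    half1 = g.subset(samples=g.sample_ids[:30])
    half2 = g.subset(samples=g.sample_ids[30:])
    combined = pd.concat([imp.transform(half1).values, imp.transform(half2).values])
    pd.testing.assert_frame_equal(combined, imp.transform(g).values)


def test_permuting_samples_permutes_rows(tiny_cohort):
    _, g, db, *_ = tiny_cohort
    imp = ExpressionImputer(db).fit(g)
    perm = list(reversed(g.sample_ids))
    em = imp.transform(g)
    em2 = imp.transform(g.subset(samples=perm))
    pd.testing.assert_frame_equal(em.values.loc[perm], em2.values)


def test_noise_free_full_coverage_recovers_truth():
    cfg = SynthConfig(n_genes=12, expression_noise_sd=0.0, seed=21)
    g, db, _, truth = simulate_cohort(cfg)
    em = impute(g, db)
    got = em.values[truth.latent.columns].to_numpy()
    assert np.array_equal(got, truth.latent.to_numpy())


# ------------------------------------------------------------ weight db IO


def test_sqlite_round_trip(tmp_path, tiny_cohort):
    _, _, db, *_ = tiny_cohort
    path = io.write_weights_sqlite(db, tmp_path / "wb.db")
    db2 = io.load_weight_db(path, tissue="wb")
    pd.testing.assert_frame_equal(
        db.weights.reset_index(drop=True), db2.weights[db.weights.columns].reset_index(drop=True)
    )
    assert db2.tissue == "wb"


def test_load_weight_db_counts(tmp_path):
    db = _db([("g1", "v0", "G", "A", 0.5), ("g1", "v1", "G", "A", 0.2), ("g2", "v2", "G", "A", 1.0)])
    path = io.write_weights_tsv(db, tmp_path / "w.tsv")
    db2 = io.load_weight_db(path)
    assert db2.genes == ["g1", "g2"]
    assert db2.snps_per_gene().to_dict() == {"g1": 2, "g2": 1}


def test_missing_weight_file_errors():
    with pytest.raises(DataError):
        io.load_weight_db("/nonexistent/file.db")
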