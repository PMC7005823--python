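import numpy as np
import pandas as pd
import pytest

from phenoprobe.feature_reduction import (
    ReductionConfig,
    drop_collinear,
    drop_correlated,
    drop_low_variance,
    reduce_features,
    variance_inflation,
)


@pytest.fixture()
def crafted_matrix():
    """10 features: 2 constant, 1 duplicate pair, 1 exact-sum trio, rest
    independent -- manual rule application retains exactly 6."""
    rng = np.random.default_rng(17)
    n = 60
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    data = {
        "const1": np.zeros(n),
        "const2": np.full(n, 3.14),
        "base": a,
        "dup_of_base": a.copy(),
        "sum_ab": a + b,
        "other_b": b,
        "ind1": rng.normal(size=n),
        "ind2": rng.normal(size=n),
        "ind3": rng.normal(size=n),
        "ind4": rng.normal(size=n),
    }
    return pd.DataFrame(data)


def test_variance_filter_drops_constant_columns(crafted_matrix):
    out, prov = drop_low_variance(crafted_matrix, 1e-8)
    assert set(prov["feature"]) == {"const1", "const2"}
    assert (prov["dropped_by"] == "variance").all()
    assert out.shape[1] == 8


def test_variance_filter_identity_when_threshold_zero(crafted_matrix):
    out, prov = drop_low_variance(crafted_matrix.drop(
        columns=["const1", "const2"]), 0.0)
    assert len(prov) == 0


def test_near_constant_column_dropped_at_hand_computed_variance():
    m = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.001],
                      "y": [0.0, 1.0, 2.0, 3.0]})
    assert m["x"].var(ddof=1) == pytest.approx(2.5e-7)
    out, prov = drop_low_variance(m, 1e-3)
    assert prov["feature"].tolist() == ["x"]
    assert list(out.columns) == ["y"]


def test_single_row_matrix_rejected():
    with pytest.raises(ValueError):
        drop_low_variance(pd.DataFrame({"x": [1.0]}), 1e-8)


def test_duplicate_and_negated_columns_dropped_greedily():
    rng = np.random.default_rng(2)
    a = rng.normal(size=30)
    m = pd.DataFrame({"a": a, "a_copy": a.copy(), "neg_a": -a,
                      "b": rng.normal(size=30)})
    out, prov = drop_correlated(m, 0.95)
    assert list(out.columns) == ["a", "b"]
    assert set(prov["feature"]) == {"a_copy", "neg_a"}
    assert (prov["statistic_value"] >= 0.999).all()


def test_three_mutually_correlated_columns_keep_first():
    rng = np.random.default_rng(4)
    a = rng.normal(size=200)
    m = pd.DataFrame({
        "c1": a + rng.normal(0, 0.05, 200),
        "c2": a + rng.normal(0, 0.05, 200),
        "c3": a + rng.normal(0, 0.05, 200),
    })
    assert (np.abs(np.corrcoef(m.T))[np.triu_indices(3, 1)] > 0.99).all()
    out, prov = drop_correlated(m, 0.95)
    assert list(out.columns) == ["c1"]
    assert prov["feature"].tolist() == ["c2", "c3"]


def test_orthogonal_columns_survive_vif_filter():
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.normal(size=(500, 4)),
                     columns=["a", "b", "c", "d"])
    out, prov = drop_collinear(m, 10.0)
    assert len(prov) == 0
    assert (variance_inflation(m) < 2).all()


def test_exact_linear_combination_removed_by_vif():
    rng = np.random.default_rng(9)
    a, b = rng.normal(size=100), rng.normal(size=100)
    m = pd.DataFrame({"a": a, "b": b, "c": a + b,
                      "ind": rng.normal(size=100)})
    out, prov = drop_collinear(m, 10.0)
    assert len(prov) == 1
    assert prov["feature"].iloc[0] in {"a", "b", "c"}
    assert (variance_inflation(out) <= 10.0).all()


def test_single_column_vif_is_one():
    m = pd.DataFrame({"x": np.arange(10.0)})
    assert variance_inflation(m).tolist() == [1.0]
    out, prov = drop_collinear(m, 10.0)
    assert len(prov) == 0


def test_crafted_matrix_reduces_to_six_with_reasons(crafted_matrix):
    red = reduce_features(crafted_matrix)
    assert red.matrix.shape[1] == 6
    reasons = dict(zip(red.provenance["feature"],
                       red.provenance["dropped_by"]))
    assert reasons["const1"] == "variance"
    assert reasons["const2"] == "variance"
    assert reasons["dup_of_base"] == "correlation"
    assert len(red.provenance) == 4
    collinear_drop = [f for f, r in reasons.items() if r == "collinearity"]
    assert len(collinear_drop) == 1
    assert collinear_drop[0] in {"base", "sum_ab", "other_b"}


def test_reduction_is_idempotent_and_conserving(crafted_matrix):
    red = reduce_features(crafted_matrix)
    assert len(red.retained) + len(red.dropped) == crafted_matrix.shape[1]
    again = reduce_features(red.matrix)
    assert again.retained == red.retained
    assert len(again.dropped) == 0


def test_row_permutation_does_not_change_retained_set(crafted_matrix):
    rng = np.random.default_rng(0)
    perm = crafted_matrix.iloc[rng.permutation(len(crafted_matrix))]
    assert (reduce_features(perm).retained ==
            reduce_features(crafted_matrix).retained)


def test_everything_dropped_raises_actionable_error():
    m = pd.DataFrame({"c1": np.ones(10), "c2": np.zeros(10)})
    with pytest.raises(ValueError, match="relax"):
        reduce_features(m)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ReductionConfig(corr_max=1.5)
    with pytest.raises(ValueError):
        ReductionConfig(vif_max=0.0)


def test_supervised_stage_keeps_discriminative_features():
    rng = np.random.default_rng(12)
    labels = np.repeat([0, 1], 40)
    m = pd.DataFrame({
        "informative": np.concatenate([rng.normal(0, 1, 40),
                                       rng.normal(3, 1, 40)]),
        "noise": rng.normal(size=80),
    })
    red = reduce_features(m, labels=labels)
    assert "informative" in red.retained
    assert "noise" in red.dropped
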