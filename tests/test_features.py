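"""Feature transforms against closed forms and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gestrisk.features import (
    FeaturePipeline,
    FeatureSelector,
    bin_statistics,
    c3_statistic,
    censor_bin_edges,
    impute_and_filter,
    polynomial_trend,
    relevance_filter,
    series_summary,
    vif_prune,
)


def test_series_summary_arithmetic():
    s = series_summary([120, 130, 140])
    assert s == {"mean": 130, "max": 140, "min": 120, "median": 130, "count": 3}


def test_series_summary_empty_and_singleton():
    empty = series_summary([])
    assert empty["count"] == 0
    assert all(np.isnan(empty[k]) for k in ("mean", "max", "min", "median"))
    one = series_summary([7.5])
    assert one == {"mean": 7.5, "max": 7.5, "min": 7.5, "median": 7.5, "count": 1}


def test_c3_hand_example():
    assert c3_statistic([1, 2, 3, 4, 5, 6], lag=2) == pytest.approx(31.5)


def test_c3_constant_series_is_cube():
    assert c3_statistic([3.0] * 8, lag=2) == pytest.approx(27.0)


def test_c3_too_short_is_absent():
    assert np.isnan(c3_statistic([1, 2, 3, 4], lag=2))


def test_c3_invalid_lag():
    with pytest.raises(ValueError):
        c3_statistic([1, 2, 3], lag=0)


def test_c3_matches_brute_force_triple_products():
    rng = np.random.default_rng(4)
    for _ in range(200):
        n = int(rng.integers(2, 51))
        lag = int(rng.integers(1, 4))
        x = rng.normal(size=n)
        expected = np.nan
        if n > 2 * lag:
            terms = [x[t + 2 * lag] * x[t + lag] * x[t] for t in range(n - 2 * lag)]
            expected = sum(terms) / (n - 2 * lag)
        got = c3_statistic(x, lag)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_trend_constant_series():
    b1, b2 = polynomial_trend([-3, -2, -1, 0], [5, 5, 5, 5])
    assert b1 == pytest.approx(0, abs=1e-10) and b2 == pytest.approx(0, abs=1e-10)


def test_trend_exact_line():
    t = np.array([-4.0, -2.0, -1.0, 0.0])
    b1, b2 = polynomial_trend(t, 2 * t)
    assert b1 == pytest.approx(2.0, abs=1e-9) and b2 == pytest.approx(0, abs=1e-9)


def test_trend_exact_parabola():
    t = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    b1, b2 = polynomial_trend(t, t**2)
    assert b1 == pytest.approx(0, abs=1e-9) and b2 == pytest.approx(1.0, abs=1e-9)


def test_trend_recovers_planted_coefficients_on_noise_free_data():
    rng = np.random.default_rng(1)
    for _ in range(30):
        t = np.sort(rng.uniform(-30, 0, size=int(rng.integers(3, 12))))
        a0, a1, a2 = rng.normal(size=3)
        b1, b2 = polynomial_trend(t, a0 + a1 * t + a2 * t**2)
        assert b1 == pytest.approx(a1, abs=1e-6)
        assert b2 == pytest.approx(a2, abs=1e-6)


def test_trend_degenerate_sizes():
    assert all(np.isnan(v) for v in polynomial_trend([0.0], [1.0]))
    b1, b2 = polynomial_trend([-1.0, 0.0], [1.0, 3.0])
    assert b1 == pytest.approx(2.0) and np.isnan(b2)


def test_bin_statistics_deltas():
    out = bin_statistics([10, 12, 100, 102], [80, 82, 90, 92], [0, 14, 20])
    assert out["bin1_mean"] == pytest.approx(81)
    assert out["bin2_mean"] == pytest.approx(91)
    assert out["delta_mean_bin1to2"] == pytest.approx(10)


def test_bin_statistics_empty_bins_absent():
    out = bin_statistics([10], [80], [0, 14, 20])
    assert out["bin1_mean"] == 80
    assert np.isnan(out["bin2_mean"]) and np.isnan(out["delta_mean_bin1to2"])


def test_bin_statistics_order_free():
    a = bin_statistics([10, 100, 12], [80, 90, 82], [0, 14, 20])
    b = bin_statistics([12, 10, 100], [82, 80, 90], [0, 14, 20])
    assert a == b


def test_bin_statistics_unsorted_edges_error():
    with pytest.raises(ValueError):
        bin_statistics([10], [80], [14, 0])


def test_censor_bin_edges_prefix():
    assert censor_bin_edges((14, 20, 24, 28, 32, 34, 36, 38), 28) == (0, 14, 20, 24, 28)


# ---------------------------------------------------------------------------
# relevance filter


def test_relevance_retains_label_copy_drops_constant():
    rng = np.random.default_rng(0)
    y = rng.random(400) < 0.3
    X = pd.DataFrame({
        "copy": y.astype(float),
        "const": np.ones(400),
        "noise": rng.normal(size=400),
    })
    res = relevance_filter(X, y)
    assert "copy" in res.retained
    assert "const" not in res.retained
    table = res.table.set_index("feature")
    assert table.loc["const", "p_value"] == 1.0
    assert (table["retained"] == (table["p_adjusted"] < 0.05)).all()


def test_relevance_null_features_mostly_dropped():
    rng = np.random.default_rng(3)
    hits = []
    for _ in range(20):
        y = rng.random(500) < 0.3
        X = pd.DataFrame(rng.normal(size=(500, 50)),
                         columns=[f"f{i}" for i in range(50)])
        hits.append(len(relevance_filter(X, y).retained))
    # BH at 5% on pure noise: almost every replicate keeps nothing
    assert np.mean([h <= 2 for h in hits]) >= 0.9


# ---------------------------------------------------------------------------
# imputation / missingness


def test_impute_median_fills_training_gaps():
    train = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0]})
    out, _, medians = impute_and_filter(train)
    assert medians["a"] == 2.0
    assert out["a"].tolist() == [1.0, 2.0, 2.0, 4.0]


def test_impute_drops_mostly_missing_column_everywhere():
    train = pd.DataFrame({"keep": np.arange(100.0),
                          "gone": [1.0] + [np.nan] * 99})
    apply = train.copy()
    tr, ap, _ = impute_and_filter(train, apply)
    assert "gone" not in tr.columns and "gone" not in ap.columns


def test_impute_identity_on_complete_data():
    train = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    out, _, _ = impute_and_filter(train)
    pd.testing.assert_frame_equal(out, train)


def test_impute_applies_train_median_to_test():
    train = pd.DataFrame({"a": [1.0, 3.0, np.nan]})
    apply = pd.DataFrame({"a": [np.nan, 10.0]})
    _, ap, _ = impute_and_filter(train, apply)
    assert ap["a"].tolist() == [2.0, 10.0]


def test_impute_all_missing_surviving_column_errors():
    train = pd.DataFrame({"a": [np.nan] * 10})
    with pytest.raises(ValueError):
        impute_and_filter(train, missingness_threshold=1.0)


# ---------------------------------------------------------------------------
# VIF pruning


def test_vif_drops_exactly_one_of_duplicated_pair():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    X = pd.DataFrame({"x1": x, "x1_dup": x, "z": rng.normal(size=200)})
    kept = vif_prune(X)
    assert "z" in kept
    assert sorted(set(["x1", "x1_dup"]) & set(kept)) in ([ "x1"], ["x1_dup"])
    assert len(kept) == 2


def test_vif_keeps_orthogonal_columns():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
    assert vif_prune(X) == list("abcde")


def test_vif_breaks_near_exact_linear_dependence():
    rng = np.random.default_rng(2)
    x1, x2 = rng.normal(size=200), rng.normal(size=200)
    x3 = x1 + x2 + rng.normal(scale=1e-4, size=200)
    X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    kept = vif_prune(X)
    assert len(kept) == 2


def test_vif_identity_below_two_columns():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    assert vif_prune(X) == ["a"]


# ---------------------------------------------------------------------------
# fitted selector: train/apply separation


def test_selector_transform_is_frozen_after_fit(cohort_2k, labels_2k):
    from gestrisk.cohort import build_timepoint_dataset

    ds = build_timepoint_dataset(cohort_2k.pregnancies, cohort_2k.events,
                                 labels_2k, 14, FeaturePipeline())
    half = len(ds.X) // 2
    dev, test = ds.X.iloc[:half], ds.X.iloc[half:]
    sel = FeatureSelector().fit(dev, ds.y.iloc[:half])
    out1 = sel.transform(test)
    out2 = sel.transform(test)
    pd.testing.assert_frame_equal(out1, out2)
    assert not out1.isna().any().any()
    assert set(sel.vif_columns_) <= set(sel.columns_)
    # medians come from the dev split only
    gaps = test[sel.columns_].isna()
    filled = out1[gaps].stack()
    expected = sel.medians_.reindex(filled.index.get_level_values(1)).to_numpy()
    assert np.allclose(filled.to_numpy(), expected)


def test_feature_matrix_pure_function_of_inputs(cohort_2k):
    pipeline = FeaturePipeline()
    ev = cohort_2k.events
    from gestrisk.cohort import censor_events

    censored = censor_events(ev, 20)
    a = pipeline.transform(cohort_2k.pregnancies, censored, 20)
    b = pipeline.transform(cohort_2k.pregnancies, censored.sample(frac=1, random_state=0), 20)
    pd.testing.assert_frame_equal(a, b)
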