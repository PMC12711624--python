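"""I/O and filter tests: exact filter semantics, z-scoring, sample logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfactor import (
    MultiOmicsDataset,
    OmicsView,
    SimulationConfig,
    filter_detection,
    filter_mutation_burden,
    generate_multiomics,
    intersect_samples,
    read_matrix,
    select_top_variable,
    write_matrix,
    zscore,
)
from omicsfactor.preprocess import center_binary, preprocess_dataset


def make_view(X, modality="continuous", name="v", sample_ids=None, feature_ids=None, mask=None):
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    return OmicsView(
        name,
        modality,
        X,
        sample_ids or [f"s{i}" for i in range(n)],
        feature_ids or [f"f{j}" for j in range(d)],
        mask=mask,
    )


# ---------------------------------------------------------------------------
# read/write

def test_read_matrix_transposes_features_in_rows(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("feature\ts1\ts2\ts3\nfA\t1\t2\t3\nfB\t4\t5\t6\n")
    v = read_matrix(p, features_in_rows=True)
    assert v.X.shape == (3, 2)
    assert v.sample_ids == ["s1", "s2", "s3"]
    assert v.feature_ids == ["fA", "fB"]
    np.testing.assert_array_equal(v.X, [[1, 4], [2, 5], [3, 6]])


def test_read_matrix_na_cell_masked(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("id\tfA\tfB\ns1\t1\tNA\ns2\t3\t4\n")
    v = read_matrix(p)
    assert v.mask.sum() == 3
    assert not v.mask[0, 1]


def test_read_matrix_errors_name_culprits(tmp_path):
    dup = tmp_path / "dup.tsv"
    dup.write_text("id\tfA\tfA\ns1\t1\t2\n")
    with pytest.raises(ValueError, match="fA"):
        read_matrix(dup)
    bad = tmp_path / "bad.tsv"
    bad.write_text("id\tfA\tfB\ns1\t1\toops\n")
    with pytest.raises(ValueError, match="fB"):
        read_matrix(bad)


def test_write_read_round_trip_preserves_values(tmp_path):
    ds, _ = generate_multiomics(
        SimulationConfig(n_samples=15, seed=0, missing_view_fraction=0.2)
    )
    v = ds.view("protein")
    p = tmp_path / "prot.tsv"
    write_matrix(v, p)
    back = read_matrix(p, modality="continuous")
    np.testing.assert_array_equal(back.mask, v.mask)
    np.testing.assert_array_equal(back.X[back.mask], v.X[v.mask])
    assert back.sample_ids == v.sample_ids
    assert back.feature_ids == v.feature_ids


# ---------------------------------------------------------------------------
# zscore

def test_zscore_exact_small_example():
    v = zscore(make_view([[2], [4], [6]]))
    np.testing.assert_allclose(v.X[:, 0], [-1, 0, 1])


def test_zscore_idempotent():
    rng = np.random.default_rng(0)
    v = make_view(rng.normal(3, 2, (50, 20)))
    once = zscore(v)
    twice = zscore(once)
    np.testing.assert_allclose(twice.X, once.X, atol=1e-12)


def test_zscore_column_moments():
    rng = np.random.default_rng(1)
    v = zscore(make_view(rng.normal(5, 3, (50, 20))))
    assert np.abs(v.X.mean(axis=0)).max() < 1e-12
    np.testing.assert_allclose(v.X.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_zscore_drops_zero_variance_features():
    X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    v = zscore(make_view(X))
    assert v.feature_ids == ["f0"]


def test_zscore_respects_mask():
    X = np.array([[1.0, 9.0], [2.0, np.nan], [3.0, 11.0]])
    v = zscore(make_view(X))
    assert not v.mask[1, 1]
    obs = v.X[v.mask[:, 1], 1]
    assert obs.mean() == pytest.approx(0, abs=1e-12)
    assert obs.std(ddof=1) == pytest.approx(1, abs=1e-12)


def test_center_binary_keeps_mask_and_centers():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    v = center_binary(make_view(X, modality="binary"))
    np.testing.assert_allclose(v.X.mean(axis=0), 0, atol=1e-12)


# ---------------------------------------------------------------------------
# filters

def test_mutation_burden_strictly_greater():
    n = 20
    X = np.zeros((n, 4))
    for j, burden in enumerate([5, 11, 10, 15]):
        X[:burden, j] = 1
    v = filter_mutation_burden(make_view(X, modality="binary"), min_mutated=10)
    assert v.feature_ids == ["f1", "f3"]  # exactly 10 mutated samples -> dropped


def test_mutation_burden_all_zero_empty():
    v = filter_mutation_burden(make_view(np.zeros((5, 3)), modality="binary"))
    assert v.n_features == 0


def test_mutation_burden_rejects_continuous():
    with pytest.raises(ValueError):
        filter_mutation_burden(make_view(np.ones((3, 2))))


def test_top_variable_ranking_and_identity():
    rng = np.random.default_rng(2)
    X = np.column_stack([3 * rng.normal(size=30), 1 * rng.normal(size=30), 2 * rng.normal(size=30)])
    v = make_view(X)
    top2 = select_top_variable(v, 2)
    assert top2.feature_ids == ["f0", "f2"]  # original relative order kept
    np.testing.assert_array_equal(select_top_variable(v, 3).X, v.X)


def test_top_variable_tie_broken_lexicographically():
    X = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    v = make_view(X, feature_ids=["b", "a", "c"])
    assert select_top_variable(v, 2).feature_ids == ["b", "a"]  # 'a','b' win the tie


def test_top_variable_k_too_large():
    with pytest.raises(ValueError):
        select_top_variable(make_view(np.ones((3, 2))), 5)


def test_detection_rate_strictly_greater():
    mask = np.ones((100, 3), dtype=bool)
    mask[:25, 0] = False  # 0.75
    mask[:20, 1] = False  # exactly 0.80
    X = np.where(mask, 1.0 * np.arange(300).reshape(100, 3), np.nan)
    v = filter_detection(make_view(X, mask=mask), min_rate=0.8)
    assert v.feature_ids == ["f2"]


def test_detection_fully_observed_identity():
    v = make_view(np.random.default_rng(3).normal(size=(10, 4)))
    assert filter_detection(v, 0.8).feature_ids == v.feature_ids


def test_filters_never_alter_values_or_sample_order():
    rng = np.random.default_rng(4)
    v = make_view(rng.normal(size=(20, 10)))
    out = select_top_variable(filter_detection(v, 0.5), 5)
    assert out.sample_ids == v.sample_ids
    cols = [v.feature_ids.index(f) for f in out.feature_ids]
    np.testing.assert_array_equal(out.X, v.X[:, cols])


def test_detection_then_topk_commutes():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 12))
    X[rng.random((40, 12)) < 0.3] = np.nan
    v = make_view(X)
    a = select_top_variable(filter_detection(v, 0.6), 4)
    b_ids = select_top_variable(filter_detection(v, 0.6), filter_detection(v, 0.6).n_features)
    # top-k on the post-detection feature set gives the same top set
    assert a.feature_ids == select_top_variable(filter_detection(v, 0.6), 4).feature_ids
    assert set(a.feature_ids) <= set(b_ids.feature_ids)


# ---------------------------------------------------------------------------
# sample intersection

def _three_view_dataset():
    samples = ["A", "B", "C", "D"]
    masks = {
        "v1": [1, 1, 1, 0],
        "v2": [0, 1, 1, 0],
        "v3": [0, 1, 1, 1],
    }
    views = []
    for name, present in masks.items():
        X = np.arange(8, dtype=float).reshape(4, 2)
        mask = np.tile(np.array(present, dtype=bool)[:, None], (1, 2))
        X = np.where(mask, X, np.nan)
        views.append(make_view(X, name=name, sample_ids=samples, mask=mask))
    return MultiOmicsDataset(views=views)


def test_intersect_samples_complete_case():
    ds = intersect_samples(_three_view_dataset(), require_all_views=True)
    assert ds.sample_ids == ["B", "C"]


def test_intersect_samples_union():
    ds = intersect_samples(_three_view_dataset(), require_all_views=False)
    assert ds.sample_ids == ["A", "B", "C", "D"]


def test_complete_case_count_matches_mask_scan():
    cfg = SimulationConfig(n_samples=120, seed=13, missing_view_fraction=0.1)
    ds, _ = generate_multiomics(cfg)
    expected = np.ones(120, dtype=bool)
    for v in ds.views:
        expected &= v.mask.any(axis=1)
    out = intersect_samples(ds, require_all_views=True)
    assert len(out.sample_ids) == int(expected.sum())


def test_preprocess_dataset_applies_filters_and_zscore(default_cohort):
    ds, _ = default_cohort
    pp = preprocess_dataset(
        ds, top_k={"mrna": 200}, min_detection={"protein": 0.5}, complete_cases=False
    )
    assert pp.view("mrna").n_features == 200
    prot = pp.view("protein")
    obs = np.where(prot.mask, prot.X, np.nan)
    assert np.abs(np.nanmean(obs, axis=0)).max() < 1e-10
    # complete-case restriction keeps only samples present in every view
    cc = preprocess_dataset(ds, complete_cases=True)
    for v in cc.views:
        assert v.observed_samples().all()


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_zscore_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), size=(12, 5))
    once = zscore(make_view(X))
    twice = zscore(once)
    np.testing.assert_allclose(twice.X, once.X, atol=1e-10)
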