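"""Factor model tests: exact recovery, matching oracles, variance accounting."""

import numpy as np
import pytest

from omicsfactor import (
    MultiOmicsDataset,
    OmicsView,
    SimulationConfig,
    ViewSpec,
    align_factors,
    fit_factor_model,
    generate_multiomics,
    load_model,
    save_model,
    variance_explained,
    zscore,
)
from omicsfactor.factor import FactorModel, FitMeta
from omicsfactor.preprocess import preprocess_dataset
from conftest import SEED


def _dataset_from_matrix(X, name="v"):
    n = X.shape[0]
    view = OmicsView(name, "continuous", X, [f"s{i}" for i in range(n)],
                     [f"f{j}" for j in range(X.shape[1])])
    return MultiOmicsDataset(views=[view])


def _noiseless_dataset(n=60, d=(40, 30), K=3, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, K))
    views = []
    for m, dm in enumerate(d):
        W = rng.standard_normal((dm, K))
        X = Z @ W.T
        views.append(
            OmicsView(f"v{m}", "continuous", X, [f"s{i}" for i in range(n)],
                      [f"f{m}_{j}" for j in range(dm)])
        )
    return MultiOmicsDataset(views=views), Z


def test_noiseless_rank3_data_recovered_exactly():
    ds, _ = _noiseless_dataset(K=3)
    model = fit_factor_model(ds, K=3, ard=False, tol=1e-12, max_iter=2000)
    ss_res = ss_tot = 0.0
    for v in ds.views:
        recon = model.Z @ model.W[v.name].T
        ss_res += np.sum((v.X - recon) ** 2)
        ss_tot += np.sum(v.X**2)
    assert ss_res / ss_tot < 1e-6


def test_planted_factors_recovered_with_surplus_capacity(matched_factors):
    """Fitting K=8 to a 5-factor cohort recovers all planted score vectors."""
    matched, C = matched_factors
    corrs = [C[r, c] for r, c in matched.items()]
    assert np.mean(corrs) >= 0.9


def test_single_view_ard_off_matches_pca_subspace():
    rng = np.random.default_rng(4)
    n, d, K = 80, 25, 3
    # strong low-rank structure with distinct strengths for a clean eigengap
    Z = rng.standard_normal((n, K)) * np.array([4.0, 3.0, 2.0])
    X = Z @ rng.standard_normal((d, K)).T + 0.05 * rng.standard_normal((n, d))
    ds = _dataset_from_matrix(X)
    model = fit_factor_model(ds, K=K, ard=False, tol=1e-15, max_iter=20000)
    U = np.linalg.svd(X, full_matrices=False)[0][:, :K]
    Qz = np.linalg.qr(model.Z)[0]
    angles = np.arccos(np.clip(np.linalg.svd(U.T @ Qz, compute_uv=False), -1, 1))
    assert angles.max() < 1e-6


def test_objective_monotone_nonincreasing(fitted_model):
    trace = np.array(fitted_model.fit_meta.objective_trace)
    rel_increase = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1.0)
    assert rel_increase.max() <= 1e-10


def test_factor_order_by_descending_variance_explained(fitted_model, processed):
    vt = variance_explained(fitted_model, processed)
    totals = vt.R2.sum(axis=1)
    assert np.all(np.diff(totals) <= 1e-9)


def test_reconstruction_invariant_under_paired_column_scaling(fitted_model):
    model = fitted_model
    scales = np.linspace(0.5, 2.0, model.K)
    recon = model.Z @ model.W["protein"].T
    recon_scaled = (model.Z * scales) @ (model.W["protein"] / scales).T
    np.testing.assert_allclose(recon, recon_scaled, atol=1e-9)


def test_k_larger_than_data_rejected():
    ds, _ = _noiseless_dataset(n=10, d=(6, 5), K=2)
    with pytest.raises(ValueError):
        fit_factor_model(ds, K=11)


# ---------------------------------------------------------------------------
# variance explained

def test_variance_zero_scores_zero_r2(processed, fitted_model):
    model = FactorModel(
        Z=np.zeros_like(fitted_model.Z),
        W=fitted_model.W,
        tau=fitted_model.tau,
        K=fitted_model.K,
        view_names=fitted_model.view_names,
        sample_ids=fitted_model.sample_ids,
        feature_ids=fitted_model.feature_ids,
        view_weights=fitted_model.view_weights,
        fit_meta=fitted_model.fit_meta,
    )
    vt = variance_explained(model, processed)
    assert np.abs(vt.R2).max() < 1e-12 or (vt.R2 <= 0).all()


def test_variance_noiseless_total_is_one():
    ds, _ = _noiseless_dataset(K=3, seed=2)
    model = fit_factor_model(ds, K=3, ard=False, tol=1e-13, max_iter=5000)
    vt = variance_explained(model, ds)
    np.testing.assert_allclose(vt.per_view_total, 1.0, atol=1e-9)
    assert vt.grand_total == pytest.approx(1.0, abs=1e-9)


def test_variance_totals_match_planted_signal_fractions(default_cohort, processed, fitted_model):
    _, truth = default_cohort
    vt = variance_explained(fitted_model, processed)
    for name, total in zip(vt.view_names, vt.per_view_total):
        assert total == pytest.approx(truth.signal_fraction_std[name], abs=0.05)


def test_planted_activity_pattern_recovered(default_cohort, processed, fitted_model, matched_factors):
    """Factor-view activity (which factor is active where) recovered at R2 > 0.01."""
    dataset, truth = default_cohort
    matched, C = matched_factors
    cfg_activity = SimulationConfig(seed=SEED).factor_view_activity
    vt = variance_explained(fitted_model, processed)
    for k_true, k_fit in matched.items():
        for m, view in enumerate(vt.view_names):
            planted_active = bool(cfg_activity[k_true, m])
            fitted_active = vt.R2[k_fit, m] > 0.01
            if view == "mutation" and planted_active:
                continue  # weak Bernoulli signal split across factors is not reliably > 1%
            assert fitted_active == planted_active, (k_true, view)


# ---------------------------------------------------------------------------
# factor alignment

def _model_from_scores(Z, sample_ids=None):
    n, K = Z.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return FactorModel(
        Z=Z, W={"v": np.zeros((3, K))}, tau={"v": 1.0}, K=K, view_names=["v"],
        sample_ids=sample_ids, feature_ids={"v": ["a", "b", "c"]},
        view_weights={"v": 1.0}, fit_meta=FitMeta(0, 0, 0.0, 0.0, True, False),
    )


def test_align_factors_permutation_and_sign_flip_exact():
    rng = np.random.default_rng(0)
    Z = rng.standard_normal((40, 5))
    perm = [3, 0, 4, 1, 2]
    signs = np.array([1, -1, 1, -1, 1])
    pairs = align_factors(_model_from_scores(Z), _model_from_scores(Z[:, perm] * signs))
    assert len(pairs) == 5
    for a, b, r in pairs:
        assert perm[b] == a
        assert abs(r) == pytest.approx(1.0, abs=1e-12)


def test_align_factors_independent_scores_low_correlation():
    high = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        pairs = align_factors(
            _model_from_scores(rng.standard_normal((100, 5))),
            _model_from_scores(rng.standard_normal((100, 5))),
        )
        high += max(abs(r) for _, _, r in pairs) >= 0.5
    assert high <= 1  # matched |corr| ~ extreme of null correlations, rarely >= 0.5


def test_refit_with_different_seed_matches_planted_factors(
    default_cohort, fitted_model, fitted_model_alt_seed, matched_factors
):
    matched, _ = matched_factors
    pairs = align_factors(fitted_model, fitted_model_alt_seed)
    planted_fit_indices = set(matched.values())
    strong = {a for a, b, r in pairs if abs(r) >= 0.9}
    assert planted_fit_indices <= strong


def test_align_factors_disjoint_samples_error():
    a = _model_from_scores(np.zeros((4, 2)), sample_ids=["a", "b", "c", "d"])
    b = _model_from_scores(np.zeros((4, 2)), sample_ids=["e", "f", "g", "h"])
    with pytest.raises(ValueError):
        align_factors(a, b)


# ---------------------------------------------------------------------------
# serialization

def test_model_container_round_trip_bit_exact(tmp_path, fitted_model):
    p = tmp_path / "model.h5"
    save_model(fitted_model, p)
    back = load_model(p)
    np.testing.assert_array_equal(back.Z, fitted_model.Z)
    for name in fitted_model.view_names:
        np.testing.assert_array_equal(back.W[name], fitted_model.W[name])
        assert back.feature_ids[name] == fitted_model.feature_ids[name]
    assert back.tau == fitted_model.tau
    assert back.sample_ids == fitted_model.sample_ids
    assert back.fit_meta.final_objective == fitted_model.fit_meta.final_objective


def test_model_container_bytes_deterministic(tmp_path, fitted_model):
    p1, p2 = tmp_path / "m1.h5", tmp_path / "m2.h5"
    save_model(fitted_model, p1)
    save_model(fitted_model, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_refit_same_seed_is_deterministic(processed):
    a = fit_factor_model(processed, K=4, seed=3, max_iter=30)
    b = fit_factor_model(processed, K=4, seed=3, max_iter=30)
    np.testing.assert_array_equal(a.Z, b.Z)
    for name in a.view_names:
        np.testing.assert_array_equal(a.W[name], b.W[name])
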