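"""Shared fixtures: one default synthetic cohort and its fitted model.

The default cohort (200 samples; views 300 binary / 1000 / 800 / 800
features; 5 true factors) is expensive enough to generate and fit that the
suite shares a single session-scoped instance; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from omicsfactor import (
    SimulationConfig,
    fit_factor_model,
    generate_multiomics,
    preprocess_dataset,
)

SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    return generate_multiomics(SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def processed(default_cohort):
    dataset, _ = default_cohort
    return preprocess_dataset(dataset, complete_cases=False)


@pytest.fixture(scope="session")
def fitted_model(processed):
    return fit_factor_model(processed, K=8, seed=SEED, ard=True)


@pytest.fixture(scope="session")
def fitted_model_alt_seed(processed):
    """Second fit of the same data under a different initialisation seed."""
    return fit_factor_model(processed, K=8, seed=SEED + 100, ard=True)


@pytest.fixture(scope="session")
def matched_factors(default_cohort, fitted_model):
    """Hungarian matching of planted factors to fitted factors by |corr|."""
    from scipy.optimize import linear_sum_assignment

    dataset, truth = default_cohort
    rows = [dataset.sample_ids.index(s) for s in fitted_model.sample_ids]
    Zt = truth.Z_true[rows]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(Zt.T, fitted_model.Z.T)[: Zt.shape[1], Zt.shape[1]:])
    C = np.nan_to_num(C)
    ri, ci = linear_sum_assignment(-C)
    return {int(r): int(c) for r, c in zip(ri, ci)}, C


@pytest.fixture(scope="session")
def validation_cohort(default_cohort):
    """Held-out cohort sharing the training cohort's planted loadings."""
    _, truth = default_cohort
    cfg = SimulationConfig(n_samples=150, seed=SEED + 1, missing_view_fraction=0.0)
    return generate_multiomics(cfg, loadings_from=truth)


def tiny_survival_config(n: int, hazard_coef: float, seed: int) -> SimulationConfig:
    """Cheap cohort (one small view) for survival simulations."""
    from omicsfactor import ViewSpec

    return SimulationConfig(
        n_samples=n,
        views=[ViewSpec("mrna", 5), ViewSpec("protein", 5)],
        n_factors_true=2,
        prognostic_factor_index=1,
        hazard_coef=hazard_coef,
        n_signature_genes=0,
        missing_view_fraction=0.0,
        seed=seed,
    )
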