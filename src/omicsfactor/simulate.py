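"""Synthetic multi-omics cohorts with planted latent structure.

The generator emulates the data-generating assumptions of a multi-view
linear factor model: a shared samples x K score matrix Z drives every view
through view-specific loading matrices W_m, continuous views with additive
Gaussian noise and a mutation-like binary view through a logistic link.
One designated factor carries the clinical signal: it sets a
proportional-hazards survival outcome, an ordinal tumour stage and, for the
first factor, a microsatellite-instability-like covariate.  A subset of
genes shared between the protein and mRNA views is planted as a high-loading
"signature" on the prognostic factor so that signature-extraction and
single-cell scoring stages have a ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import BINARY, CONTINUOUS, ClinicalTable, MultiOmicsDataset, OmicsView


@dataclass
class ViewSpec:
    name: str
    n_features: int
    modality: str = CONTINUOUS
    noise_sd: float = 1.0


def default_views() -> list[ViewSpec]:
    """Four views echoing the mutation / mRNA / protein / phospho size asymmetry."""
    return [
        ViewSpec("mutation", 300, BINARY, 0.0),
        ViewSpec("mrna", 1000, CONTINUOUS, 1.0),
        ViewSpec("protein", 800, CONTINUOUS, 1.0),
        ViewSpec("phospho", 800, CONTINUOUS, 1.0),
    ]


def default_activity(n_factors: int, n_views: int) -> np.ndarray:
    """Factor x view activity mask: mostly active, a few planted holes."""
    act = np.ones((n_factors, n_views), dtype=bool)
    if n_views >= 4 and n_factors >= 4:
        act[1, 0] = False   # prognostic factor absent from the mutation view
        act[3, 3] = False
    return act


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    Defaults give a desk-scale cohort: 200 samples, four views sized
    300 (binary) / 1000 / 800 / 800, five true factors, unit observation
    noise, a prognostic factor with log-hazard -0.7 per unit score, 30%
    censoring and 10% of samples missing any given view.
    """

    n_samples: int = 200
    views: list[ViewSpec] = field(default_factory=default_views)
    n_factors_true: int = 5
    loading_sparsity: float = 0.3
    factor_view_activity: np.ndarray | None = None
    prognostic_factor_index: int = 1
    hazard_coef: float = -0.7
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    stage_link_strength: float = 1.0
    missing_view_fraction: float = 0.1
    n_signature_genes: int = 30
    signature_loading: float = 3.0
    signature_loading_mrna: float = 1.5
    binary_loading_scale: float = 0.4
    factor_strengths: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors_true < 1:
            raise ValueError("n_factors_true must be >= 1")
        for name, frac in [
            ("loading_sparsity", self.loading_sparsity),
            ("censoring_rate", self.censoring_rate),
            ("missing_view_fraction", self.missing_view_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.factor_view_activity is None:
            self.factor_view_activity = default_activity(self.n_factors_true, len(self.views))
        self.factor_view_activity = np.asarray(self.factor_view_activity, dtype=bool)
        if self.factor_view_activity.shape != (self.n_factors_true, len(self.views)):
            raise ValueError(
                f"factor_view_activity shape {self.factor_view_activity.shape} does not "
                f"match ({self.n_factors_true} factors, {len(self.views)} views)"
            )
        if not self.factor_view_activity.any(axis=0).all():
            raise ValueError("every view must have at least one active factor")
        if not 0 <= self.prognostic_factor_index < self.n_factors_true:
            raise ValueError("prognostic_factor_index out of range")
        if self.factor_strengths is None:
            # distinct strengths make factors identifiable (eigengap), the
            # way real latent factors are separated by variance explained
            self.factor_strengths = 1.6 * 0.8 ** np.arange(self.n_factors_true)
        self.factor_strengths = np.asarray(self.factor_strengths, dtype=float)
        if self.factor_strengths.shape != (self.n_factors_true,):
            raise ValueError("factor_strengths must have one entry per true factor")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated cohort, for recovery tests.

    ``signal_fraction`` per view is the planted fraction of total sum of
    squares attributable to the factor part: SS(ZW')/SS(Y) for continuous
    views, and for the binary view the analogous ratio built from the
    column-centred Bernoulli means.  ``signal_fraction_std`` is the same
    quantity on the per-feature standardised scale (the unweighted mean of
    per-feature fractions), which is what a fit on z-scored data sees.
    """

    Z_true: np.ndarray
    W_true: dict[str, np.ndarray]
    signature_genes: list[str]
    hazard_coef: float
    stage_labels: np.ndarray
    signal_fraction: dict[str, float]
    signal_fraction_std: dict[str, float]
    prognostic_factor_index: int


def _loadings(rng: np.random.Generator, config: SimulationConfig) -> dict[str, np.ndarray]:
    K = config.n_factors_true
    W: dict[str, np.ndarray] = {}
    for m, vs in enumerate(config.views):
        scale = config.binary_loading_scale if vs.modality == BINARY else 1.0
        w = rng.normal(0.0, scale, size=(vs.n_features, K)) * config.factor_strengths
        w[rng.random((vs.n_features, K)) < config.loading_sparsity] = 0.0
        w[:, ~config.factor_view_activity[:, m]] = 0.0
        W[vs.name] = w
    return W


def _plant_signature(
    rng: np.random.Generator, config: SimulationConfig, W: dict[str, np.ndarray]
) -> list[str]:
    """Give the signature genes dominant, single-factor, negative loadings.

    Signature genes live in both the protein and mRNA views under shared
    gene ids; their loadings on every non-prognostic factor are zeroed so
    the cross-layer mRNA-protein correlation is driven by the planted factor
    alone, mirroring a coordinated ECM programme.
    """
    names = {vs.name for vs in config.views}
    if config.n_signature_genes == 0 or not {"protein", "mrna"} <= names:
        return []
    k = config.prognostic_factor_index
    n_prot = next(vs.n_features for vs in config.views if vs.name == "protein")
    n_mrna = next(vs.n_features for vs in config.views if vs.name == "mrna")
    n_shared = min(n_prot, n_mrna)
    if config.n_signature_genes > n_shared:
        raise ValueError("more signature genes than shared protein/mRNA features")
    idx = rng.choice(n_shared, size=config.n_signature_genes, replace=False)
    for view, load in [("protein", config.signature_loading), ("mrna", config.signature_loading_mrna)]:
        W[view][idx, :] = 0.0
        W[view][idx, k] = -load * rng.uniform(0.9, 1.1, size=idx.size)
    # keep background loadings on the prognostic factor small in the protein
    # view so the planted set is separable after weight normalisation
    bg = np.ones(n_prot, dtype=bool)
    bg[idx] = False
    W["protein"][bg, k] = rng.normal(0.0, 0.15 * config.signature_loading, size=bg.sum())
    return [_gene_id(i) for i in idx]


def _gene_id(i: int) -> str:
    return f"G{i + 1:05d}"


def _feature_ids(view: ViewSpec) -> list[str]:
    if view.name in ("protein", "mrna"):
        return [_gene_id(i) for i in range(view.n_features)]
    return [f"{view.name}_f{i + 1:05d}" for i in range(view.n_features)]


def _ordinal_from_latent(latent: np.ndarray, n_levels: int = 4) -> np.ndarray:
    """Ordinal labels 1..n_levels by fixed quantile thresholds on a latent score."""
    qs = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
    return 1 + np.searchsorted(qs, latent, side="left").astype(int)


def _censoring_bound(t: np.ndarray, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring giving expected censoring ``rate``.

    For C ~ U(0, c), P(censored | T = t) = min(t / c, 1); the expected
    censored fraction is monotone decreasing in c, solved by bisection.
    """
    if rate <= 0:
        return np.inf
    if rate >= 1:
        return float(np.min(t)) * 0.5

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(t / c, 1.0))) - rate

    lo, hi = float(np.min(t)) * 1e-3, float(np.max(t)) * 1e3
    return brentq(frac, lo, hi)


def generate_multiomics(
    config: SimulationConfig, loadings_from: SyntheticTruth | None = None
) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Simulate a multi-omics cohort with planted factors, survival and stage.

    Pass ``loadings_from`` (the truth of a previously generated cohort) to
    reuse its loading matrices and signature genes with freshly drawn
    samples — a validation cohort measuring the same features under the
    same latent biology.

    Continuous views are Y_m = Z W_m' + eps with eps ~ N(0, noise_sd^2);
    the binary view draws Bernoulli(logistic(Z W_m')) and is exposed both as
    raw 0/1 values and, in the truth bookkeeping, through its column-centred
    means. Survival times are exponential with log-hazard
    ``hazard_coef * z_prognostic``; censoring is independent uniform
    administrative censoring calibrated to ``censoring_rate``. A fraction of
    samples has each view fully masked (never all views for one sample).
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_samples, config.n_factors_true
    Z = rng.standard_normal((n, K))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)

    if loadings_from is not None:
        expected = {vs.name: (vs.n_features, K) for vs in config.views}
        got = {name: W.shape for name, W in loadings_from.W_true.items()}
        if expected != got:
            raise ValueError(f"template loadings {got} do not match configured views {expected}")
        W = {name: Wm.copy() for name, Wm in loadings_from.W_true.items()}
        signature = list(loadings_from.signature_genes)
    else:
        W = _loadings(rng, config)
        signature = _plant_signature(rng, config, W)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    views: list[OmicsView] = []
    signal_fraction: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    # blockwise view missingness, cycled so no sample loses every view
    order = rng.permutation(n)
    n_miss = int(round(config.missing_view_fraction * n))
    for m, vs in enumerate(config.views):
        miss = np.zeros(n, dtype=bool)
        if n_miss:
            start = (m * n_miss) % n
            take = np.arange(start, start + n_miss) % n
            miss[order[take]] = True
        masks[vs.name] = miss

    signal_fraction_std: dict[str, float] = {}
    for vs in config.views:
        signal = Z @ W[vs.name].T
        if vs.modality == BINARY:
            p = expit(signal)
            X = (rng.random((n, vs.n_features)) < p).astype(float)
            mu = p.mean(axis=0, keepdims=True)
            sig_d = np.sum((p - mu) ** 2, axis=0)
            tot_d = sig_d + np.sum(p * (1 - p), axis=0)
        else:
            X = signal + rng.normal(0.0, vs.noise_sd, size=(n, vs.n_features))
            sig_d = np.sum(signal**2, axis=0)
            tot_d = np.sum(X**2, axis=0)
        ss_sig, ss_tot = float(sig_d.sum()), float(tot_d.sum())
        signal_fraction[vs.name] = ss_sig / ss_tot if ss_tot > 0 else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_d = np.where(tot_d > 0, sig_d / tot_d, 0.0)
        signal_fraction_std[vs.name] = float(frac_d.mean())
        mask = np.ones_like(X, dtype=bool)
        mask[masks[vs.name], :] = False
        X = X.copy()
        X[~mask] = np.nan
        views.append(
            OmicsView(vs.name, vs.modality, X, sample_ids, _feature_ids(vs), mask=mask)
        )

    z_prog = Z[:, config.prognostic_factor_index]
    hazard = config.baseline_hazard * np.exp(config.hazard_coef * z_prog)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c_max = _censoring_bound(t_event, config.censoring_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event

    # low prognostic-factor score <-> advanced stage
    stage_latent = -config.stage_link_strength * z_prog + rng.standard_normal(n)
    stage = _ordinal_from_latent(stage_latent, 4)
    # MSI-like 3-level covariate tied (negatively) to factor 1
    msi_latent = -1.5 * Z[:, 0] + rng.standard_normal(n)
    msi = _ordinal_from_latent(msi_latent, 3) - 1  # 0=MSS, 1=MSI-L, 2=MSI-H
    msi_label = np.array(["MSS", "MSI-L", "MSI-H"])[msi]

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "stage": stage,
                "msi_status": msi_label,
                "age": np.round(rng.normal(65, 10, size=n), 1),
                "sex": rng.choice(["F", "M"], size=n),
                "site": rng.choice(["colon", "rectum"], size=n),
                "metastasis": rng.choice(["M0", "M1"], size=n, p=[0.8, 0.2]),
                "time": time,
                "event": event,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = SyntheticTruth(
        Z_true=Z,
        W_true=W,
        signature_genes=signature,
        hazard_coef=config.hazard_coef,
        stage_labels=stage,
        signal_fraction=signal_fraction,
        signal_fraction_std=signal_fraction_std,
        prognostic_factor_index=config.prognostic_factor_index,
    )
    return MultiOmicsDataset(views=views, clinical=clinical), truth


def generate_sc_counts(
    n_cells: int,
    n_genes: int,
    cell_types: list[str],
    signature_genes: list[str],
    fold_change: float,
    seed: int,
    designated_type: str | None = None,
    dispersion: float = 2.0,
    tumour_type_ratio: float = 5.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial single-cell counts with one signature-high cell type.

    Gene base means are log-normal; signature genes' means are multiplied by
    ``fold_change`` in ``designated_type`` (default: first label). The
    designated type is ``tumour_type_ratio`` times more frequent in cells
    labelled tumour than in normal tissue, so tissue-level positive-cell
    fractions have a planted ratio.

    Returns (counts cell x gene, cell-type labels, tissue labels).
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if not signature_genes:
        raise ValueError("signature_genes must be non-empty")
    rng = np.random.default_rng(seed)
    genes = [_gene_id(i) for i in range(n_genes)]
    missing = set(signature_genes) - set(genes)
    if missing:
        raise ValueError(f"signature genes outside gene universe: {sorted(missing)[:5]}")
    designated = designated_type or cell_types[0]
    if designated not in cell_types:
        raise ValueError(f"designated type {designated!r} not in cell_types")

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    sig_idx = np.array([genes.index(g) for g in signature_genes])

    tissue = pd.Series(
        rng.choice(["tumour", "normal"], size=n_cells), name="tissue"
    )
    others = [t for t in cell_types if t != designated]
    base_p = 1.0 / (tumour_type_ratio + len(others))
    labels = np.empty(n_cells, dtype=object)
    for tis, p_des in [("tumour", tumour_type_ratio * base_p), ("normal", base_p)]:
        rows = np.flatnonzero(tissue.values == tis)
        probs = [p_des] + [(1 - p_des) / len(others)] * len(others) if others else [1.0]
        labels[rows] = rng.choice([designated] + others, size=rows.size, p=probs)
    labels = pd.Series(labels, name="cell_type")

    mean = np.tile(base_mean, (n_cells, 1))
    boost_rows = labels.values == designated
    mean[np.ix_(boost_rows, sig_idx)] *= fold_change
    # NB via Gamma-Poisson: shape = dispersion, scale = mean / dispersion
    lam = rng.gamma(dispersion, mean / dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    counts = pd.DataFrame(counts, index=[f"cell{i + 1:05d}" for i in range(n_cells)], columns=genes)
    labels.index = counts.index
    tissue.index = counts.index
    return counts, labels, tissue
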