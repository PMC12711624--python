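"""Multi-view Gaussian latent factor model with ARD shrinkage.

The model decomposes several samples x features matrices sharing a sample
universe as Y_m ~ Z W_m' + E_m, with a common samples x K score matrix Z,
view-specific loading matrices W_m and per-view residual variance tau_m.
Missing entries (including whole missing views for a sample) are excluded
from every sufficient statistic; no imputation enters the fit.

Estimation is MAP coordinate ascent: a standard-normal prior on the rows of
Z, a per-(factor, view) automatic relevance determination (ARD) prior
N(0, 1/alpha_km) on loadings that shrinks factor-view pairs carrying no
signal, and exact coordinate updates for Z, W, tau and alpha.  Each update
minimises the penalized objective exactly, so the objective is monotone
non-increasing across sweeps.  With ``ard=False`` all priors are dropped and
the procedure is plain alternating least squares, whose fixed point on a
single fully-observed view spans the top-K principal component subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import MultiOmicsDataset

log = logging.getLogger(__name__)

ALPHA_MIN, ALPHA_MAX = 1e-6, 1e8


@dataclass
class FitMeta:
    seed: int
    iterations: int
    tolerance: float
    final_objective: float
    converged: bool
    ard: bool
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class FactorModel:
    """Fitted multi-view factor model.

    Z columns are ordered by descending total variance explained and scaled
    to unit sample SD, with the compensating scale absorbed into W; the sign
    of each factor is fixed so its largest-|loading| entry is positive.
    """

    Z: np.ndarray
    W: dict[str, np.ndarray]
    tau: dict[str, float]
    K: int
    view_names: list[str]
    sample_ids: list[str]
    feature_ids: dict[str, list[str]]
    view_weights: dict[str, float]
    fit_meta: FitMeta

    def loadings(self, view_name: str) -> np.ndarray:
        return self.W[view_name]


@dataclass
class VarianceTable:
    """Variance explained per factor per view, as fractions of observed SS."""

    R2: np.ndarray              # K x n_views
    per_view_total: np.ndarray  # n_views
    grand_total: float
    view_names: list[str] = field(default_factory=list)


def _masked_views(dataset: MultiOmicsDataset):
    """Return (names, filled matrices, masks, per-row-constant flags)."""
    names, Ys, masks, uniform = [], [], [], []
    for v in dataset.views:
        names.append(v.name)
        Ys.append(v.filled(0.0))
        masks.append(v.mask)
        row_any = v.mask.any(axis=1)
        row_all = v.mask.all(axis=1)
        uniform.append(bool(np.all(row_any == row_all)))
    return names, Ys, masks, uniform


def _init_svd(Ys, masks, weights, K: int, seed: int) -> np.ndarray:
    """Deterministic init: SVD of the row-concatenated, view-weighted data.

    Missing entries are zero-imputed for initialisation only. ``seed`` fixes
    the sign convention of the singular vectors.
    """
    blocks = []
    for Y, mask, w in zip(Ys, masks, weights):
        obs = Y[mask]
        sd = obs.std() if obs.size else 1.0
        blocks.append(Y * (w / max(sd, 1e-12)))
    X = np.concatenate(blocks, axis=1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    K_eff = min(K, len(s))
    Z = U[:, :K_eff] * s[:K_eff]
    if K_eff < K:
        rng = np.random.default_rng(seed)
        Z = np.concatenate([Z, rng.standard_normal((Z.shape[0], K - K_eff)) * 1e-3], axis=1)
    # deterministic sign: largest-|entry| coordinate positive
    for k in range(Z.shape[1]):
        j = int(np.argmax(np.abs(Z[:, k])))
        if Z[j, k] < 0:
            Z[:, k] = -Z[:, k]
    return Z


def _objective(Ys, masks, weights, Z, Ws, taus, alphas, ard: bool) -> float:
    """Penalized negative log posterior up to additive constants."""
    total = 0.0
    for Y, mask, w, W_m, tau, alpha in zip(Ys, masks, weights, Ws, taus, alphas):
        R = (Y - Z @ W_m.T) * mask
        n_obs = mask.sum()
        total += w * (0.5 * np.sum(R * R) / tau + 0.5 * n_obs * np.log(tau))
        if ard:
            # prior scaled by the view weight so shrinkage strength relative
            # to the (weighted) likelihood is the same in every view
            ss_w = np.sum(W_m * W_m, axis=0)
            D = W_m.shape[0]
            total += w * (0.5 * np.sum(alpha * ss_w) - 0.5 * D * np.sum(np.log(alpha)))
    if ard:
        total += 0.5 * np.sum(Z * Z)
    return float(total)


def fit_factor_model(
    dataset: MultiOmicsDataset,
    K: int = 15,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
    ard: bool = True,
) -> FactorModel:
    """Fit the K-factor model by monotone MAP coordinate ascent.

    Views are weighted inversely to the square root of their feature count
    so a large view (e.g. phospho-proteome) cannot dominate the shared
    scores by size alone. Expects continuous views z-scored and the
    mutation-like binary view centred beforehand.

    Convergence: relative change of the penalized objective below ``tol``.
    A non-converged model is returned with ``fit_meta.converged = False``
    and a logged warning.
    """
    names, Ys, masks, uniform = _masked_views(dataset)
    n = Ys[0].shape[0]
    D_total = sum(Y.shape[1] for Y in Ys)
    if K > min(n, D_total):
        raise ValueError(f"K={K} exceeds min(n_samples={n}, total features={D_total})")
    weights = [1.0 / np.sqrt(Y.shape[1]) for Y in Ys]

    Z = _init_svd(Ys, masks, weights, K, seed)
    Ws = [np.zeros((Y.shape[1], K)) for Y in Ys]
    taus = [1.0] * len(Ys)
    alphas = [np.ones(K) for _ in Ys]
    eye = np.eye(K)

    obj_prev = np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # --- W update: per-feature ridge regression on observed samples
        for m, (Y, mask, w) in enumerate(zip(Ys, masks, weights)):
            prior = taus[m] * np.diag(alphas[m]) if ard else 1e-10 * eye
            if uniform[m]:
                rows = mask.any(axis=1)
                G = Z[rows].T @ Z[rows]
                Ws[m] = np.linalg.solve(G + prior, Z[rows].T @ Y[rows]).T
            else:
                G = np.einsum("nd,nk,nl->dkl", mask, Z, Z, optimize=True)
                rhs = (Y * mask).T @ Z
                Ws[m] = np.linalg.solve(G + prior[None, :, :], rhs[:, :, None])[:, :, 0]

        # --- Z update: per-sample ridge across all observed views
        A = np.tile((eye if ard else 1e-10 * eye)[None], (n, 1, 1)).copy()
        b = np.zeros((n, K))
        for m, (Y, mask, w) in enumerate(zip(Ys, masks, weights)):
            c = w / taus[m]
            if uniform[m]:
                rows = mask.any(axis=1)
                WtW = Ws[m].T @ Ws[m]
                A[rows] += c * WtW
                b[rows] += c * (Y[rows] @ Ws[m])
            else:
                A += c * np.einsum("nd,dk,dl->nkl", mask, Ws[m], Ws[m], optimize=True)
                b += c * ((Y * mask) @ Ws[m])
        Z = np.linalg.solve(A, b[:, :, None])[:, :, 0]

        # --- tau update: mean squared residual over observed entries
        for m, (Y, mask) in enumerate(zip(Ys, masks)):
            R = (Y - Z @ Ws[m].T) * mask
            n_obs = mask.sum()
            taus[m] = max(float(np.sum(R * R) / max(n_obs, 1)), 1e-12)

        # --- ARD precision update (exact minimiser, clipped to a wide box)
        if ard:
            for m, W_m in enumerate(Ws):
                D = W_m.shape[0]
                ss = np.sum(W_m * W_m, axis=0)
                alphas[m] = np.clip(D / np.maximum(ss, 1e-300), ALPHA_MIN, ALPHA_MAX)

        obj = _objective(Ys, masks, weights, Z, Ws, taus, alphas, ard)
        trace.append(obj)
        if np.isfinite(obj_prev):
            denom = max(abs(obj_prev), 1.0)
            if abs(obj_prev - obj) / denom < tol:
                converged = True
                obj_prev = obj
                break
        obj_prev = obj

    if not converged:
        log.warning("factor model did not converge in %d iterations (tol=%g)", max_iter, tol)

    W = {name: W_m for name, W_m in zip(names, Ws)}
    tau = {name: t for name, t in zip(names, taus)}
    model = FactorModel(
        Z=Z,
        W=W,
        tau=tau,
        K=K,
        view_names=names,
        sample_ids=list(dataset.sample_ids),
        feature_ids={v.name: list(v.feature_ids) for v in dataset.views},
        view_weights={name: w for name, w in zip(names, weights)},
        fit_meta=FitMeta(seed, it, tol, float(obj_prev), converged, ard, trace),
    )
    _canonicalise(model, dataset)
    return model


def _canonicalise(model: FactorModel, dataset: MultiOmicsDataset) -> None:
    """Fix the scale/sign/order gauge of the fitted factors, in place.

    Each factor's score column is rescaled to unit sample SD (scale absorbed
    into the loadings), the sign set so the largest-|loading| entry is
    positive, and columns ordered by descending total variance explained.
    Reconstruction Z W' is unchanged.
    """
    sd = model.Z.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    model.Z = model.Z / sd
    for name in model.view_names:
        model.W[name] = model.W[name] * sd

    for k in range(model.K):
        stacked = np.concatenate([model.W[name][:, k] for name in model.view_names])
        j = int(np.argmax(np.abs(stacked)))
        if stacked[j] < 0:
            model.Z[:, k] = -model.Z[:, k]
            for name in model.view_names:
                model.W[name][:, k] = -model.W[name][:, k]

    vt = variance_explained(model, dataset)
    totals = vt.R2.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    model.Z = model.Z[:, order]
    for name in model.view_names:
        model.W[name] = model.W[name][:, order]


def variance_explained(model: FactorModel, dataset: MultiOmicsDataset) -> VarianceTable:
    """Per-factor, per-view R^2 over observed entries.

    R2[k, m] = 1 - SS(Y_m - z_k w_mk') / SS(Y_m); the per-view total uses
    the full reconstruction Z W_m', and the grand total is the
    feature-count-weighted mean of per-view totals.
    """
    names = [v.name for v in dataset.views]
    if set(names) != set(model.view_names):
        raise ValueError(f"model views {model.view_names} != dataset views {names}")
    K = model.K
    R2 = np.zeros((K, len(names)))
    totals = np.zeros(len(names))
    sizes = np.zeros(len(names))
    for m, v in enumerate(dataset.views):
        if list(v.feature_ids) != model.feature_ids[v.name]:
            raise ValueError(f"view {v.name!r}: feature ids differ from the fitted model")
        Y = v.filled(0.0)
        mask = v.mask
        W_m = model.W[v.name]
        ss_tot = float(np.sum((Y * mask) ** 2))
        sizes[m] = v.n_features
        if ss_tot == 0:
            continue
        for k in range(K):
            R = (Y - np.outer(model.Z[:, k], W_m[:, k])) * mask
            R2[k, m] = 1.0 - float(np.sum(R * R)) / ss_tot
        Rfull = (Y - model.Z @ W_m.T) * mask
        totals[m] = 1.0 - float(np.sum(Rfull * Rfull)) / ss_tot
    grand = float(np.sum(totals * sizes) / np.sum(sizes))
    return VarianceTable(R2=R2, per_view_total=totals, grand_total=grand, view_names=names)


def align_factors(model_a: FactorModel, model_b: FactorModel) -> list[tuple[int, int, float]]:
    """One-to-one factor matching between two fits sharing sample ids.

    Solves the assignment maximising the summed |Pearson correlation|
    between score columns (Hungarian algorithm); returns
    (factor_a, factor_b, signed correlation) triples sorted by factor_a.
    """
    shared = [s for s in model_a.sample_ids if s in set(model_b.sample_ids)]
    if not shared:
        raise ValueError("models share no samples")
    ia = [model_a.sample_ids.index(s) for s in shared]
    ib = [model_b.sample_ids.index(s) for s in shared]
    Za, Zb = model_a.Z[ia], model_b.Z[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(Za.T, Zb.T)[: model_a.K, model_a.K:]
    C = np.nan_to_num(C)  # ARD-pruned factors have constant scores
    rows, cols = linear_sum_assignment(-np.abs(C))
    return sorted(
        [(int(r), int(c), float(C[r, c])) for r, c in zip(rows, cols)], key=lambda t: t[0]
    )


# ---------------------------------------------------------------------------
# model container (HDF5, layout version 1)

_LAYOUT_VERSION = 1


def save_model(model: FactorModel, path) -> None:
    """Serialise a model to one hierarchical container file.

    Layout v1: root attrs (K, layout_version, fit metadata); datasets
    ``scores`` + ``sample_ids``; per-view groups ``views/<name>`` with
    ``loadings``, ``feature_ids``, and attrs ``tau``/``weight``. Written
    without HDF5 timestamps so identical models produce identical bytes.
    """
    str_dt = h5py.string_dtype("utf-8")

    def mkds(grp, name, data):
        grp.create_dataset(name, data=data, track_times=False)

    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["layout_version"] = _LAYOUT_VERSION
        f.attrs["K"] = model.K
        meta = model.fit_meta
        for key in ("seed", "iterations", "tolerance", "final_objective", "converged", "ard"):
            f.attrs[f"fit_{key}"] = getattr(meta, key)
        mkds(f, "scores", model.Z)
        mkds(f, "sample_ids", np.array(model.sample_ids, dtype=str_dt))
        mkds(f, "view_order", np.array(model.view_names, dtype=str_dt))
        views = f.create_group("views")
        for name in model.view_names:
            g = views.create_group(name)
            mkds(g, "loadings", model.W[name])
            mkds(g, "feature_ids", np.array(model.feature_ids[name], dtype=str_dt))
            g.attrs["tau"] = model.tau[name]
            g.attrs["weight"] = model.view_weights[name]


def load_model(path) -> FactorModel:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["layout_version"])
        if version != _LAYOUT_VERSION:
            raise ValueError(f"unsupported model container layout v{version}")
        names = [s.decode() for s in f["view_order"][()]]
        meta = FitMeta(
            seed=int(f.attrs["fit_seed"]),
            iterations=int(f.attrs["fit_iterations"]),
            tolerance=float(f.attrs["fit_tolerance"]),
            final_objective=float(f.attrs["fit_final_objective"]),
            converged=bool(f.attrs["fit_converged"]),
            ard=bool(f.attrs["fit_ard"]),
        )
        return FactorModel(
            Z=f["scores"][()],
            W={n: f[f"views/{n}/loadings"][()] for n in names},
            tau={n: float(f[f"views/{n}"].attrs["tau"]) for n in names},
            K=int(f.attrs["K"]),
            view_names=names,
            sample_ids=[s.decode() for s in f["sample_ids"][()]],
            feature_ids={
                n: [s.decode() for s in f[f"views/{n}/feature_ids"][()]] for n in names
            },
            view_weights={n: float(f[f"views/{n}"].attrs["weight"]) for n in names},
            fit_meta=meta,
        )
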