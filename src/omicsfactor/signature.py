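"""Varimax rotation of loadings and thresholded gene-signature extraction.

A factor's raw loading vector mixes many weak contributions; an orthogonal
varimax rotation concentrates weight onto few features per factor, after
which simple weight thresholds define a gene signature. The extracted set
can be further required to behave coherently across molecular layers
(protein-mRNA correlation), yielding a cross-layer-validated signature
suitable for single-cell module scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import MultiOmicsDataset
from .factor import FactorModel

log = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """A gene signature with rotated weights and the thresholds behind it."""

    factor_index: int
    genes: list[str]
    weights: dict[str, float]
    thresholds: tuple[float, float]   # (weight_thresh, corr_thresh)
    provenance: dict[str, str]

    def __len__(self) -> int:
        return len(self.genes)


def varimax_criterion(W: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = W**2
    return float(np.sum(np.mean(sq**2, axis=0) - np.mean(sq, axis=0) ** 2))


def varimax(
    W: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    kaiser_normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Classic varimax rotation (SVD form of the Lawley-Maxwell iteration).

    Finds an orthogonal R maximising the varimax criterion of W R; returns
    (W R, R). The criterion is non-decreasing across sweeps. K = 1 returns
    the identity rotation. Kaiser row-normalisation (rows scaled to unit
    communality during rotation) is off by default.
    """
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValueError("loadings contain non-finite values")
    D, K = W.shape
    if K == 1:
        return W.copy(), np.eye(1)
    comm = None
    if kaiser_normalize:
        comm = np.sqrt(np.sum(W**2, axis=1))
        comm[comm == 0] = 1.0
        W = W / comm[:, None]
    R = np.eye(K)
    crit_prev = varimax_criterion(W)
    for _ in range(max_iter):
        L = W @ R
        # gradient of the criterion wrt R, up to scale
        G = W.T @ (L**3 - L * np.mean(L**2, axis=0, keepdims=True))
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        crit = varimax_criterion(W @ R)
        if crit - crit_prev < tol * max(crit_prev, 1e-12):
            break
        crit_prev = crit
    W_rot = W @ R
    if kaiser_normalize:
        W_rot = W_rot * comm[:, None]
    return W_rot, R


def varimax_aligned(W: np.ndarray, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Varimax with rotated columns re-matched to the input columns.

    Rotation permutes and sign-flips factors arbitrarily; this wrapper
    reorders the rotated columns (Hungarian assignment on |R|) and fixes
    signs so rotated factor k is the one most aligned with input factor k.
    Lets callers keep referring to factors by their pre-rotation index.
    """
    W_rot, R = varimax(W, **kwargs)
    rows, cols = linear_sum_assignment(-np.abs(R))
    perm = np.empty_like(rows)
    perm[rows] = cols
    signs = np.sign(R[rows, cols])
    signs[signs == 0] = 1.0
    R_al = R[:, perm] * signs[None, :]
    return W @ R_al, R_al


def top_fraction_features(
    weights: np.ndarray | pd.Series, feature_ids: list[str] | None = None, fraction: float = 0.10
) -> list[str]:
    """Ids of the ceil(fraction * D) features with largest |weight|.

    Ties are broken lexicographically by feature id.
    """
    if isinstance(weights, pd.Series):
        feature_ids = [str(i) for i in weights.index]
        weights = weights.to_numpy(dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty weight vector")
    if feature_ids is None or len(feature_ids) != weights.size:
        raise ValueError("feature_ids must match weights")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_top = int(np.ceil(fraction * weights.size))
    order = sorted(range(weights.size), key=lambda i: (-abs(weights[i]), feature_ids[i]))
    return [feature_ids[i] for i in order[:n_top]]


def _orient_negative(w: np.ndarray) -> np.ndarray:
    """Flip sign so the largest-|weight| feature loads negatively.

    ECM-type prognostic factors conventionally carry their top features with
    negative sign (low factor score = high programme activity); fixing this
    orientation makes absolute-weight thresholds reproducible.
    """
    j = int(np.argmax(np.abs(w)))
    return -w if w[j] > 0 else w.copy()


def rotated_factor_weights(
    model: FactorModel, factor_index: int, view: str = "protein",
    kaiser_normalize: bool = False,
) -> pd.Series:
    """Varimax-rotated, max-|weight|-normalised weights of one factor.

    The view's loading matrix is varimax-rotated (columns re-aligned to the
    input factors), the requested factor's column oriented so its top
    feature is negative, and scaled to unit maximum absolute weight — the
    scale on which thresholds like 0.5 / 0.74 are meaningful.
    """
    W = model.W[view]
    W_rot, _ = varimax_aligned(W, kaiser_normalize=kaiser_normalize)
    w = _orient_negative(W_rot[:, factor_index])
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak
    return pd.Series(w, index=model.feature_ids[view], name=f"factor{factor_index}")


def cross_layer_correlation(
    dataset: MultiOmicsDataset, genes: list[str], views: tuple[str, str] = ("mrna", "protein")
) -> pd.Series:
    """Per-gene Pearson correlation between two views over common samples."""
    va, vb = (dataset.view(v) for v in views)
    fa = {f: i for i, f in enumerate(va.feature_ids)}
    fb = {f: i for i, f in enumerate(vb.feature_ids)}
    out = {}
    for g in genes:
        if g not in fa or g not in fb:
            out[g] = np.nan
            continue
        xa, ma = va.X[:, fa[g]], va.mask[:, fa[g]]
        xb, mb = vb.X[:, fb[g]], vb.mask[:, fb[g]]
        both = ma & mb
        if both.sum() < 3:
            out[g] = np.nan
            continue
        x, y = xa[both], xb[both]
        if x.std() == 0 or y.std() == 0:
            out[g] = np.nan
            continue
        out[g] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out)


def extract_signature(
    model: FactorModel,
    dataset: MultiOmicsDataset,
    factor_index: int,
    weight_thresh: float = 0.5,
    corr_thresh: float | None = 0.5,
    weight_view: str = "protein",
    corr_views: tuple[str, str] = ("mrna", "protein"),
    kaiser_normalize: bool = False,
) -> SignatureSet:
    """Derive a gene signature from one factor's rotated loadings.

    Pipeline: varimax-rotate the ``weight_view`` loadings, keep genes with
    |rotated, max-normalised weight| > ``weight_thresh`` on the chosen
    factor, then (if ``corr_thresh`` is not None) keep genes whose
    protein-mRNA Pearson correlation across common samples exceeds
    ``corr_thresh``. A stricter ``weight_thresh`` with ``corr_thresh=None``
    gives the refined, more focused signature variant. An empty result is
    returned (with a warning), not raised.
    """
    weights = rotated_factor_weights(model, factor_index, weight_view, kaiser_normalize)
    candidates = weights[weights.abs() > weight_thresh]
    genes = list(candidates.index)
    if corr_thresh is not None and genes:
        corr = cross_layer_correlation(dataset, genes, corr_views)
        genes = [g for g in genes if np.isfinite(corr[g]) and corr[g] > corr_thresh]
    if not genes:
        log.warning("signature extraction produced an empty gene set (factor %d)", factor_index)
    return SignatureSet(
        factor_index=factor_index,
        genes=genes,
        weights={g: float(weights[g]) for g in genes},
        thresholds=(weight_thresh, corr_thresh if corr_thresh is not None else -np.inf),
        provenance={"weight_view": weight_view, "corr_views": "+".join(corr_views)},
    )


def write_signature(sig: SignatureSet, path: str | Path) -> None:
    pd.Series(sig.weights, name="weight").rename_axis("gene").to_csv(Path(path), sep="\t")


def read_signature(path: str | Path, factor_index: int = 0) -> SignatureSet:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    weights = {str(g): float(w) for g, w in df.iloc[:, 0].items()}
    return SignatureSet(
        factor_index=factor_index,
        genes=list(weights),
        weights=weights,
        thresholds=(np.nan, np.nan),
        provenance={"source": str(path)},
    )
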