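"""Least-squares projection of new cohorts onto a pre-trained factor model.

Scoring a validation cohort on frozen loadings W amounts to solving
Y ~ Z W' for Z, i.e. Z = Y pinv(W'), the Moore-Penrose least-squares
solution (W is features x K and non-square, so "matrix inversion of the
model's weights" can only mean the pseudo-inverse). For a single factor
this reduces to Y w / (w'w).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import OmicsView
from .factor import FactorModel

log = logging.getLogger(__name__)


@dataclass
class ProjectionResult:
    """Projected factor scores with feature-matching diagnostics.

    ``conditioning`` is the smallest retained singular value of the matched
    loading matrix: small values flag unstable projections.
    """

    scores: np.ndarray            # samples x len(factors); NaN where unscoreable
    sample_ids: list[str]
    factors: list[int]
    matched_features: int
    dropped_features: list[str]
    conditioning: float


def _normalise_id(fid: str) -> str:
    """Case-fold and strip a trailing dotted version suffix (e.g. ``.2``)."""
    fid = fid.casefold()
    head, _, tail = fid.rpartition(".")
    if head and tail.isdigit():
        return head
    return fid


def project_cohort(
    model: FactorModel,
    view: OmicsView,
    view_name: str | None = None,
    factors: list[int] | None = None,
    rcond: float = 1e-10,
    normalise_ids: bool = False,
) -> ProjectionResult:
    """Score a cohort view on the model's loadings by least squares.

    The view must already be z-scored with the new cohort's own means/SDs.
    Feature ids are matched exactly against the model's loading rows
    (optionally after case-folding/version stripping); unmatched features on
    either side are dropped and reported. Missing entries in a sample are
    excluded from that sample's normal equations; a sample with no observed
    matched feature gets NaN scores.
    """
    view_name = view_name or view.name
    if view_name not in model.W:
        raise KeyError(f"model has no view {view_name!r}; has {model.view_names}")
    factors = list(range(model.K)) if factors is None else list(factors)
    if any(not 0 <= f < model.K for f in factors):
        raise IndexError(f"factor indices {factors} outside 0..{model.K - 1}")

    model_ids = model.feature_ids[view_name]
    key = _normalise_id if normalise_ids else (lambda s: s)
    lookup = {}
    for i, fid in enumerate(model_ids):
        lookup.setdefault(key(fid), i)
    cohort_cols, model_rows, matched_ids = [], [], set()
    for j, fid in enumerate(view.feature_ids):
        i = lookup.get(key(fid))
        if i is not None and key(fid) not in matched_ids:
            cohort_cols.append(j)
            model_rows.append(i)
            matched_ids.add(key(fid))
    dropped = [f for j, f in enumerate(view.feature_ids) if j not in set(cohort_cols)]
    dropped += [f for f in model_ids if key(f) not in matched_ids]
    n_matched = len(cohort_cols)
    if n_matched < len(factors):
        raise ValueError(
            f"only {n_matched} features matched between cohort and model view "
            f"{view_name!r}, fewer than the {len(factors)} requested factors"
        )
    if dropped:
        log.info("projection onto %r: matched %d features, dropped %d", view_name, n_matched, len(dropped))

    W = model.W[view_name][np.ix_(model_rows, factors)]      # D_matched x F
    Y = view.X[:, cohort_cols]
    mask = view.mask[:, cohort_cols]
    Yf = np.where(mask, Y, 0.0)

    svals = np.linalg.svd(W, compute_uv=False)
    cutoff = rcond * svals.max() if svals.size else 0.0
    conditioning = float(svals[svals > cutoff].min()) if (svals > cutoff).any() else 0.0

    n = Y.shape[0]
    scores = np.full((n, len(factors)), np.nan)
    complete = mask.all(axis=1)
    if complete.any():
        pinvWt = np.linalg.pinv(W.T, rcond=rcond)             # F x D -> D x F? (pinv of W': D x F)
        scores[complete] = Yf[complete] @ pinvWt
    for i in np.flatnonzero(~complete):
        obs = mask[i]
        if not obs.any():
            continue
        sol, *_ = np.linalg.lstsq(W[obs], Yf[i, obs], rcond=rcond)
        scores[i] = sol
    return ProjectionResult(
        scores=scores,
        sample_ids=list(view.sample_ids),
        factors=factors,
        matched_features=n_matched,
        dropped_features=dropped,
        conditioning=conditioning,
    )


def stratify_scores(scores: np.ndarray, rule: str = "median", q: float | None = None,
                    threshold: float | None = None) -> np.ndarray:
    """Split scores into ``"low"`` / ``"high"`` groups.

    Rules: ``median`` (cut at the sample median), ``quantile`` (cut at the
    q-quantile, so a fraction q of samples is low), ``threshold`` (fixed
    cut-point). Ties at the cut go to the low group.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite for stratification")
    if np.ptp(scores) == 0:
        raise ValueError("cannot stratify constant scores")
    if rule == "median":
        cut = float(np.median(scores))
    elif rule == "quantile":
        if q is None or not 0 < q < 1:
            raise ValueError("quantile rule needs q in (0, 1)")
        cut = float(np.quantile(scores, q))
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs a threshold")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return np.where(scores <= cut, "low", "high")
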