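"""Single-cell gene module scoring with expression-bin-matched controls.

The module score of a cell is the mean normalized expression of the
signature genes minus the mean expression of control genes drawn from the
same dataset-average expression bins — the binned-control scheme introduced
for cell-cycle and programme scoring in single-cell analysis. Matching
controls by expression level cancels depth and baseline-abundance effects,
so a random gene set scores around zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .signature import SignatureSet

log = logging.getLogger(__name__)


@dataclass
class ModuleScoreResult:
    per_cell_score: pd.Series
    signature_used: list[str]
    controls_per_gene: int
    bins: int
    per_type_summary: pd.DataFrame | None = None

    def summarize_by(self, labels: pd.Series) -> pd.DataFrame:
        """Mean/median score and cell count per label."""
        df = pd.DataFrame({"score": self.per_cell_score, "label": labels})
        out = df.groupby("label", observed=True)["score"].agg(["mean", "median", "count"])
        return out.sort_values("mean", ascending=False)


def lognormalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Library-size scale each cell to ``target_sum`` then log1p."""
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    return np.log1p(counts.div(lib, axis=0) * target_sum)


def module_score(
    expr: pd.DataFrame,
    signature: SignatureSet | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Score each cell for a gene signature against bin-matched controls.

    ``expr`` is a cells x genes log-normalized expression matrix. Genes are
    ranked by dataset-average expression (ties broken by gene id) and cut
    into ``n_bins`` equal-frequency bins; each signature gene contributes
    ``n_ctrl`` control genes drawn uniformly from its bin (signature genes
    excluded; with replacement when a bin is smaller than ``n_ctrl``). The
    score is mean(signature) - mean(pooled controls) per cell, deterministic
    given ``seed``.
    """
    genes = list(signature.genes) if isinstance(signature, SignatureSet) else list(signature)
    if not genes:
        raise ValueError("empty signature")
    present = [g for g in genes if g in expr.columns]
    missing = [g for g in genes if g not in expr.columns]
    if not present:
        raise ValueError(f"no signature genes found in the expression matrix; missing {missing[:10]}")
    if missing:
        log.info("module score: %d of %d signature genes absent (e.g. %s)", len(missing), len(genes), missing[:5])
    if expr.shape[1] < n_bins:
        raise ValueError(f"need >= {n_bins} genes to form {n_bins} expression bins")

    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=0)
    order = sorted(expr.columns, key=lambda g: (avg[g], g))
    bin_of = pd.Series(
        np.minimum((np.arange(len(order)) * n_bins) // len(order), n_bins - 1), index=order
    )
    sig_set = set(present)
    control_pool: list[str] = []
    for g in present:
        members = [x for x in order if bin_of[x] == bin_of[g] and x not in sig_set]
        if not members:
            log.warning("module score: bin of gene %s has no non-signature genes; gene contributes no controls", g)
            continue
        replace = len(members) < n_ctrl
        control_pool.extend(rng.choice(members, size=n_ctrl, replace=replace))

    sig_mean = expr[present].mean(axis=1)
    ctrl_mean = (
        expr[control_pool].mean(axis=1) if control_pool else pd.Series(0.0, index=expr.index)
    )
    score = sig_mean - ctrl_mean
    return ModuleScoreResult(
        per_cell_score=score.rename("module_score"),
        signature_used=present,
        controls_per_gene=n_ctrl,
        bins=n_bins,
    )


def positive_fraction(
    result: ModuleScoreResult,
    tissue_labels: pd.Series,
    threshold: float = 0.0,
    cell_mask: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-tissue fraction of score-positive cells and the tumour/normal ratio.

    A cell counts as positive when its score exceeds ``threshold`` and, if
    ``cell_mask`` is given, it belongs to the masked cell type (e.g.
    myofibroblasts); the denominator is always every cell of the tissue, so
    the fraction measures the tissue-level abundance of positive cells of
    that type. The ratio's 95% CI comes from ``n_boot`` bootstrap resamples
    of cells within each tissue; tissues with zero cells are excluded with a
    warning, and an undefined ratio (no positive normal cells, or a missing
    tissue) is reported as NaN.
    """
    score = result.per_cell_score
    tissue = tissue_labels.reindex(score.index)
    keep = tissue.notna()
    score, tissue = score[keep], tissue[keep]
    positive = (score > threshold).to_numpy()
    if cell_mask is not None:
        positive &= cell_mask.reindex(score.index).fillna(False).astype(bool).to_numpy()

    fractions: dict[str, float] = {}
    groups: dict[str, np.ndarray] = {}
    for t in pd.unique(tissue):
        pos = positive[(tissue == t).to_numpy()]
        if pos.size == 0:
            log.warning("tissue %r has zero cells; excluded", t)
            continue
        groups[str(t)] = pos
        fractions[str(t)] = float(pos.mean())

    out = {"fractions": fractions, "threshold": threshold, "ratio": np.nan, "ratio_ci95": (np.nan, np.nan)}
    if "tumour" in groups and "normal" in groups and fractions["normal"] > 0:
        out["ratio"] = fractions["tumour"] / fractions["normal"]
        rng = np.random.default_rng(seed)
        boots = []
        tum, nor = groups["tumour"], groups["normal"]
        for _ in range(n_boot):
            ft = rng.choice(tum, size=tum.size).mean()
            fn = rng.choice(nor, size=nor.size).mean()
            if fn > 0:
                boots.append(ft / fn)
        if boots:
            out["ratio_ci95"] = tuple(np.quantile(boots, [0.025, 0.975]))
    return out


# ---------------------------------------------------------------------------
# readers

def read_mtx_counts(matrix_path, genes_path, barcodes_path) -> pd.DataFrame:
    """Read 10x-style triplet counts (genes x cells MTX) as cells x genes."""
    m = mmread(str(matrix_path)).tocsr().T
    genes = [line.split("\t")[0].strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    cells = [line.strip() for line in Path(barcodes_path).read_text().splitlines() if line.strip()]
    return pd.DataFrame(m.toarray(), index=cells, columns=genes)


def read_dense_counts(path) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)
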