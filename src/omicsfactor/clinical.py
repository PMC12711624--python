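"""Associations between factor scores and clinical variables.

Continuous / ordinal / binary clinical variables are tested against each
factor with Pearson correlation (ordinal variables integer-encoded, e.g.
stage I-IV as 1-4 and MSS < MSI-L < MSI-H as 0-2); multi-level categorical
variables go through a Kruskal-Wallis rank test instead. BH FDR runs once
across the whole factor x variable correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable
from .enrich import bh_fdr

log = logging.getLogger(__name__)

#: default integer encodings for ordinal / binary clinical variables
DEFAULT_ENCODING: dict[str, dict] = {
    "msi_status": {"MSS": 0, "MSI-L": 1, "MSI-H": 2},
    "sex": {"F": 0, "M": 1},
    "metastasis": {"M0": 0, "M1": 1},
}


@dataclass
class AssociationResult:
    factor_index: int
    variable: str
    r: float
    p: float
    fdr: float
    n_used: int


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value on n-2 df.

    Pairs with a missing value on either side are dropped; needs at least 3
    complete pairs and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kruskal_wallis(scores, group_labels) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank ties, tie-corrected) with chi-square p."""
    scores = np.asarray(scores, dtype=float)
    groups = pd.Series(group_labels)
    ok = np.isfinite(scores) & groups.notna().to_numpy()
    scores, groups = scores[ok], groups[ok]
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [scores[(groups == g).to_numpy()] for g in levels]
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def _encode(series: pd.Series, variable: str, encoding: dict[str, dict]) -> pd.Series | None:
    """Numeric encoding of one clinical column, or None if not encodable."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    mapping = encoding.get(variable)
    if mapping is not None:
        unknown = set(series.dropna().unique()) - set(mapping)
        if unknown:
            raise ValueError(f"variable {variable!r}: no encoding for levels {sorted(unknown)}")
        return series.map(mapping).astype(float)
    return None


def factor_clinical_matrix(
    Z: np.ndarray,
    clinical: ClinicalTable,
    variables: list[str] | None = None,
    encoding: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Pearson-correlate every factor with every encodable clinical variable.

    Returns a tidy frame (factor, variable, r, p, fdr, n); FDR is one BH
    pass over all tested pairs. Multi-level categoricals without an ordinal
    encoding are skipped with a log message (use :func:`kruskal_wallis`);
    pairs with constant input are flagged with NaN r/p and excluded from
    the BH family.
    """
    encoding = {**DEFAULT_ENCODING, **(encoding or {})}
    df = clinical.data
    variables = variables or [c for c in df.columns if c not in ("time", "event")]
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise KeyError(f"unknown clinical variables {unknown}")
    Z = np.asarray(Z, dtype=float)
    rows = []
    for var in variables:
        enc = _encode(df[var], var, encoding)
        if enc is None:
            log.info("variable %r: multi-level categorical, skipped from Pearson matrix", var)
            continue
        y = enc.to_numpy()
        for k in range(Z.shape[1]):
            x = Z[:, k]
            ok = np.isfinite(x) & np.isfinite(y)
            n_used = int(ok.sum())
            try:
                r, p = pearson_test(x, y)
            except ValueError:
                rows.append((k, var, np.nan, np.nan, n_used))
                continue
            rows.append((k, var, r, p, n_used))
    out = pd.DataFrame(rows, columns=["factor", "variable", "r", "p", "n"])
    out["fdr"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out[["factor", "variable", "r", "p", "fdr", "n"]]
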