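"""Reading, filtering and normalisation of omics matrices and clinical tables.

Filters follow the conventions of proteogenomic cohort studies: mutated
genes kept when mutated in strictly more than a minimum number of samples,
miRNA/mRNA ranked by per-feature standard deviation, proteomic features kept
above a strict detection-rate cutoff, and complete-case sample intersection
across views.  All continuous views are z-scored per feature; the binary
mutation view is centred only.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BINARY, CONTINUOUS, ClinicalTable, MultiOmicsDataset, OmicsView

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "NaN", "nan", "N/A", "null"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(
    path: str | Path,
    name: str | None = None,
    modality: str = CONTINUOUS,
    features_in_rows: bool = False,
) -> OmicsView:
    """Read a delimited samples x features matrix into an :class:`OmicsView`.

    The first column holds ids, the header row the other axis's ids; empty
    and NA cells become masked entries. Set ``features_in_rows`` when the
    file is features x samples (it is transposed on read).
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if not features_in_rows:  # header row holds the feature ids
        dupes = sorted({f for f in header if header.count(f) > 1})
        if dupes:
            raise ValueError(f"{path}: duplicate feature ids {dupes}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False,
        float_precision="round_trip",
    )
    if features_in_rows:
        df = df.T
    bad = df.columns[df.columns.duplicated()].unique().tolist()
    if bad:
        raise ValueError(f"{path}: duplicate feature ids {bad}")
    for j, col in enumerate(df.columns):
        vals = df[col]
        if vals.dtype == object:
            coerced = pd.to_numeric(vals, errors="coerce")
            culprit = vals[coerced.isna() & vals.notna()]
            if len(culprit):
                i = culprit.index[0]
                raise ValueError(
                    f"{path}: non-numeric cell at sample {i!r}, feature {col!r}: {culprit.iloc[0]!r}"
                )
            df[col] = coerced
    return OmicsView(
        name=name or path.stem,
        modality=modality,
        X=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
    )


def write_matrix(view: OmicsView, path: str | Path) -> None:
    """Write a view to delimited text; masked entries become NA cells.

    Floats are written with 17 significant digits so a write-read round
    trip reproduces values bit-exactly.
    """
    view.to_frame().to_csv(
        Path(path), sep=_sep_for(path), index_label="sample_id", na_rep="NA",
        float_format="%.17g",
    )


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(Path(path), sep=_sep_for(path), index_label="sample_id", na_rep="NA")


def zscore(view: OmicsView) -> OmicsView:
    """Z-score each feature over its observed entries (mean 0, SD 1, ddof=1).

    Features whose observed values have zero variance (or fewer than two
    observations) have no defined z-score and are dropped with a warning.
    """
    if view.modality != CONTINUOUS:
        raise ValueError(f"zscore expects a continuous view, got {view.modality!r}")
    X = view.X.copy()
    X[~view.mask] = np.nan
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    n_obs = view.mask.sum(axis=0)
    ok = (n_obs >= 2) & np.isfinite(sd) & (sd > 0)
    if not ok.all():
        dropped = [view.feature_ids[i] for i in np.flatnonzero(~ok)]
        log.warning(
            "view %r: dropping %d zero-variance/under-observed features at z-scoring (e.g. %s)",
            view.name, len(dropped), dropped[:5],
        )
    Xz = (X - mean) / np.where(ok, sd, 1.0)
    Xz[~view.mask] = np.nan
    out = replace(view, X=Xz, mask=view.mask.copy())
    return out.subset_features(ok)


def center_binary(view: OmicsView) -> OmicsView:
    """Centre a binary view per feature (no scaling), keeping the mask."""
    if view.modality != BINARY:
        raise ValueError(f"center_binary expects a binary view, got {view.modality!r}")
    X = view.X.copy()
    X[~view.mask] = np.nan
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(X, axis=0)
    Xc = X - mean
    Xc[~view.mask] = np.nan
    return replace(view, name=view.name, modality=CONTINUOUS, X=Xc, mask=view.mask.copy())


def filter_mutation_burden(view: OmicsView, min_mutated: int = 10) -> OmicsView:
    """Keep genes mutated in strictly more than ``min_mutated`` samples."""
    if view.modality != BINARY:
        raise ValueError("mutation-burden filter applies to binary views only")
    burden = np.where(view.mask, view.X == 1.0, False).sum(axis=0)
    return view.subset_features(burden > min_mutated)


def select_top_variable(view: OmicsView, k: int) -> OmicsView:
    """Keep the k features with the largest SD over observed entries.

    Kept features stay in their original relative order; ties at the cutoff
    are broken by lexicographic feature id.
    """
    if view.modality != CONTINUOUS:
        raise ValueError("top-variable selection applies to continuous views")
    if k > view.n_features:
        raise ValueError(f"k={k} exceeds feature count {view.n_features}")
    X = view.X.copy()
    X[~view.mask] = np.nan
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd), sd, -np.inf)
    order = sorted(range(view.n_features), key=lambda i: (-sd[i], view.feature_ids[i]))
    keep = np.zeros(view.n_features, dtype=bool)
    keep[order[:k]] = True
    return view.subset_features(keep)


def filter_detection(view: OmicsView, min_rate: float = 0.8) -> OmicsView:
    """Keep features observed in strictly more than ``min_rate`` of samples."""
    if view.modality != CONTINUOUS:
        raise ValueError("detection-rate filter applies to continuous views")
    rate = view.mask.mean(axis=0)
    return view.subset_features(rate > min_rate)


def intersect_samples(dataset: MultiOmicsDataset, require_all_views: bool = True) -> MultiOmicsDataset:
    """Restrict to complete-case samples (present in every view) or the union.

    A sample counts as present in a view when it has at least one observed
    entry there. Sample order is canonicalised by id.
    """
    present = {
        v.name: {s for s, ok in zip(v.sample_ids, v.observed_samples()) if ok}
        for v in dataset.views
    }
    if require_all_views:
        keep = set.intersection(*present.values())
        if not keep:
            raise ValueError("no sample is observed in every view")
    else:
        keep = set.union(*present.values())
    return dataset.subset_samples(sorted(keep))


def attach_clinical(dataset: MultiOmicsDataset, clinical: ClinicalTable) -> MultiOmicsDataset:
    """Inner-join clinical rows onto the dataset's sample universe."""
    shared = [s for s in dataset.sample_ids if s in clinical.data.index]
    unmatched = sorted(set(dataset.sample_ids) - set(shared))
    if unmatched:
        log.warning("clinical join: %d samples without clinical rows (e.g. %s)", len(unmatched), unmatched[:5])
    ds = dataset.subset_samples(shared)
    ds.clinical = clinical.subset_samples(shared)
    return ds


def preprocess_dataset(
    dataset: MultiOmicsDataset,
    min_mutated: int = 10,
    top_k: dict[str, int] | None = None,
    min_detection: dict[str, float] | None = None,
    complete_cases: bool = True,
) -> MultiOmicsDataset:
    """Standard pipeline: per-view filters, z-scoring/centring, complete cases.

    ``top_k`` maps view names to most-variable feature counts (e.g. miRNA
    100, mRNA 1000); ``min_detection`` maps view names to detection-rate
    cutoffs (e.g. protein and phospho 0.8). SDs for the top-variable filter
    are computed on pre-z-scored values. With ``complete_cases=False``
    samples missing whole views are kept (the factor model handles them);
    the default mirrors the restriction to patients with every omics layer
    available.
    """
    top_k = top_k or {}
    min_detection = min_detection or {}
    out: list[OmicsView] = []
    for v in dataset.views:
        if v.modality == BINARY:
            v = filter_mutation_burden(v, min_mutated)
            v = center_binary(v)
        else:
            if v.name in min_detection:
                v = filter_detection(v, min_detection[v.name])
            if v.name in top_k:
                v = select_top_variable(v, min(top_k[v.name], v.n_features))
            v = zscore(v)
        out.append(v)
    ds = MultiOmicsDataset(views=out, clinical=dataset.clinical)
    if complete_cases:
        return intersect_samples(ds, require_all_views=True)
    return ds
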