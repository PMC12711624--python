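"""In-memory containers for multi-view omics data.

A *view* is one modality's samples x features matrix (somatic mutation,
miRNA, mRNA, protein, phospho-site ...). Views of one cohort share a sample
universe but have their own feature spaces; any entry, or a sample's whole
view, may be unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"

MODALITIES = (CONTINUOUS, BINARY)


@dataclass
class OmicsView:
    """One modality's samples x features matrix with a missingness mask.

    Parameters
    ----------
    name
        Modality label (e.g. ``"protein"``).
    modality
        ``"continuous"`` or ``"binary"`` (mutation-like 0/1 data).
    X
        float array, samples x features. Unobserved entries hold NaN and
        are additionally flagged in ``mask``.
    sample_ids, feature_ids
        Ordered labels for rows / columns.
    mask
        Boolean array, same shape as ``X``; True where observed.
    """

    name: str
    modality: str
    X: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"view {self.name!r}: X must be 2-D, got {self.X.ndim}-D")
        if self.modality not in MODALITIES:
            raise ValueError(f"view {self.name!r}: unknown modality {self.modality!r}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, d = self.X.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError(
                f"view {self.name!r}: shape {self.X.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.feature_ids)} feature ids"
            )
        if len(set(self.feature_ids)) != d:
            dupes = sorted({f for f in self.feature_ids if self.feature_ids.count(f) > 1})
            raise ValueError(f"view {self.name!r}: duplicate feature ids {dupes}")
        if self.mask is None:
            self.mask = ~np.isnan(self.X)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.X.shape:
            raise ValueError(f"view {self.name!r}: mask shape {self.mask.shape} != X shape {self.X.shape}")
        # NaN entries can never count as observed
        self.mask = self.mask & ~np.isnan(self.X)
        if self.modality == BINARY:
            obs = self.X[self.mask]
            if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError(f"view {self.name!r}: binary view contains values other than 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def filled(self, value: float = 0.0) -> np.ndarray:
        """X with unobserved entries replaced by ``value``."""
        out = self.X.copy()
        out[~self.mask] = value
        return out

    def observed_samples(self) -> np.ndarray:
        """Boolean vector: sample has at least one observed entry in this view."""
        return self.mask.any(axis=1)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsView":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"view {self.name!r}: unknown sample ids {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return replace(self, X=self.X[rows], mask=self.mask[rows], sample_ids=list(sample_ids))

    def subset_features(self, keep: np.ndarray) -> "OmicsView":
        """Restrict to a boolean or integer feature index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        feats = [self.feature_ids[i] for i in keep]
        return replace(self, X=self.X[:, keep], mask=self.mask[:, keep], feature_ids=feats)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out[~self.mask] = np.nan
        return pd.DataFrame(out, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival outcome.

    ``data`` is indexed by sample id; recognised columns include ``stage``
    (ordinal 0-4), ``msi_status``, ``age``, ``sex``, ``site``,
    ``metastasis``, ``time`` (follow-up, >0) and ``event`` (0/1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("clinical table: duplicate sample ids")
        self.data.index = self.data.index.astype(str)
        if "event" in self.data:
            ev = self.data["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("clinical table: event must be 0/1")
        if "time" in self.data:
            t = self.data["time"].dropna()
            if (t <= 0).any():
                raise ValueError("clinical table: follow-up time must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, sample_ids: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class MultiOmicsDataset:
    """Ordered collection of views over one sample universe, plus clinical data."""

    views: list[OmicsView] = field(default_factory=list)
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("dataset needs at least one view")
        names = [v.name for v in self.views]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate view names in {names}")
        universe = self.views[0].sample_ids
        for v in self.views[1:]:
            if v.sample_ids != universe:
                raise ValueError(
                    f"view {v.name!r} sample ids differ from view {self.views[0].name!r}; "
                    "align views before constructing the dataset"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.views[0].sample_ids)

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def view(self, name: str) -> OmicsView:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(f"no view named {name!r}; have {self.view_names}")

    def subset_samples(self, sample_ids: list[str]) -> "MultiOmicsDataset":
        clin = self.clinical
        if clin is not None:
            keep = [s for s in sample_ids if s in clin.data.index]
            clin = ClinicalTable(clin.data.loc[keep].copy())
        return MultiOmicsDataset(
            views=[v.subset_samples(sample_ids) for v in self.views], clinical=clin
        )
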