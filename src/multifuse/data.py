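"""Aligned multi-view datasets: containers, I/O, and fold-safe standardization.

A *view* is one data modality (clinical variables, laboratory results,
radiomics features, viral-genome encodings ...) measured on an overlapping
set of samples.  Analyses downstream require the views to be row-aligned on
a common sample ordering; :func:`align_views` restricts every view to the
intersection of sample identifiers, mirroring the cohort-subsetting style of
multimodal studies where each modality is available for a different subset
of patients.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "MultiViewDataset",
    "Standardizer",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_outcome",
    "align_views",
    "standardize",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """A named samples × features numeric matrix with identifier metadata."""

    view_name: str
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        n, p = values.shape if values.ndim == 2 else (len(values), -1)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if p != len(self.feature_names):
            raise ValueError(f"{p} columns but {len(self.feature_names)} feature names")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample identifiers in view {self.view_name!r}")
        if len(set(self.feature_names)) != p:
            raise ValueError(f"duplicate feature names in view {self.view_name!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Return the sub-matrix for ``ids`` in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return FeatureMatrix(self.view_name, tuple(ids), self.feature_names,
                             self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.feature_names))


@dataclass(frozen=True)
class MultiViewDataset:
    """Row-aligned collection of views plus an optional binary outcome."""

    views: tuple[FeatureMatrix, ...]
    sample_ids: tuple[str, ...]
    outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        for v in self.views:
            if v.sample_ids != self.sample_ids:
                raise ValueError(f"view {v.view_name!r} is not aligned to the dataset")
        if self.outcome is not None:
            y = np.asarray(self.outcome, dtype=int)
            if y.shape != (len(self.sample_ids),):
                raise ValueError("outcome length does not match sample count")
            if not set(np.unique(y)) <= {0, 1}:
                raise ValueError("outcome must be binary 0/1")
            object.__setattr__(self, "outcome", y)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def view_names(self) -> tuple[str, ...]:
        return tuple(v.view_name for v in self.views)

    def view(self, name: str) -> FeatureMatrix:
        for v in self.views:
            if v.view_name == name:
                return v
        raise KeyError(name)

    def matrices(self) -> list[np.ndarray]:
        return [v.values for v in self.views]

    def take_samples(self, ids: Sequence[str]) -> "MultiViewDataset":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        outcome = None if self.outcome is None else self.outcome[rows]
        return MultiViewDataset(
            tuple(v.take_samples(ids) for v in self.views), tuple(ids), outcome)


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_feature_matrix(path: str | Path, view_name: str | None = None) -> FeatureMatrix:
    """Read a CSV/TSV feature matrix (first column = sample identifier).

    The delimiter is sniffed from the header line, so `.csv` and `.tsv`
    twins of the same table parse identically.  Non-numeric payload cells
    and duplicated identifiers raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty file: {path}")
    delim = _sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"no feature columns in {path}")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate sample identifiers {dups} in {path}")
    payload = df.iloc[:, 1:]
    try:
        values = payload.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric payload in {path}: {exc}") from exc
    return FeatureMatrix(
        view_name or path.stem, tuple(ids), tuple(map(str, payload.columns)), values)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a feature matrix so that a read round-trip is bit-identical.

    Floats are serialized with ``repr`` (shortest round-trip representation),
    so finite doubles survive write → read exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["sample_id", *fm.feature_names])
        for sid, row in zip(fm.sample_ids, fm.values):
            writer.writerow([sid, *(repr(float(x)) for x in row)])


def read_outcome(path: str | Path) -> pd.Series:
    """Read an outcome CSV with columns ``sample_id,outcome`` (0/1)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if not {"sample_id", "outcome"} <= set(df.columns):
        raise ValueError("outcome file needs columns sample_id,outcome")
    s = pd.Series(df["outcome"].astype(int).to_numpy(),
                  index=df["sample_id"].astype(str))
    if s.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in outcome file")
    if not set(s.unique()) <= {0, 1}:
        raise ValueError("outcome must be coded 0/1")
    return s


def align_views(
    views: Iterable[FeatureMatrix],
    outcome: pd.Series | None = None,
    drop_missing: bool = True,
) -> MultiViewDataset:
    """Restrict views (and outcome) to their common samples, sorted.

    The intersection is taken over all view sample-id sets (and the outcome
    index, when given); the retained samples are ordered lexicographically
    so that repeated runs are deterministic.  Rows containing missing values
    are dropped first, with a logged count per view.
    """
    views = list(views)
    if len(views) < 2:
        raise ValueError("need at least two views to align")
    if drop_missing:
        cleaned = []
        for v in views:
            keep = np.isfinite(v.values).all(axis=1)
            if not keep.all():
                logger.warning("view %s: dropping %d rows with missing values",
                               v.view_name, int((~keep).sum()))
            cleaned.append(FeatureMatrix(
                v.view_name,
                tuple(s for s, k in zip(v.sample_ids, keep) if k),
                v.feature_names, v.values[keep]))
        views = cleaned
    common: set[str] = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if outcome is not None:
        common &= set(outcome.index)
    if not common:
        raise ValueError("empty sample intersection across views")
    order = tuple(sorted(common))
    for v in views:
        logger.info("align: view %s n=%d -> %d", v.view_name, v.n_samples, len(order))
    aligned = tuple(v.take_samples(order) for v in views)
    y = None if outcome is None else outcome.loc[list(order)].to_numpy()
    return MultiViewDataset(aligned, order, y)


@dataclass
class Standardizer:
    """Per-view column standardization with reusable transform parameters.

    ``fit`` learns means and standard deviations (``ddof=1``) on training
    rows; ``transform`` applies the same affine map to any other rows, which
    is what keeps cross-validation folds leakage-free.  Zero-variance
    columns are dropped with a warning.
    """

    means: dict[str, np.ndarray] = field(default_factory=dict)
    sds: dict[str, np.ndarray] = field(default_factory=dict)
    kept: dict[str, np.ndarray] = field(default_factory=dict)

    def fit(self, dataset: MultiViewDataset) -> "Standardizer":
        for v in dataset.views:
            m = v.values.mean(axis=0)
            s = v.values.std(axis=0, ddof=1)
            keep = s > 0
            if not keep.all():
                logger.warning("view %s: dropping %d zero-variance columns",
                               v.view_name, int((~keep).sum()))
            if not keep.any():
                raise ValueError(f"view {v.view_name!r} has no non-constant columns")
            self.means[v.view_name] = m[keep]
            self.sds[v.view_name] = s[keep]
            self.kept[v.view_name] = keep
        return self

    def transform(self, dataset: MultiViewDataset) -> MultiViewDataset:
        out = []
        for v in dataset.views:
            keep = self.kept[v.view_name]
            z = (v.values[:, keep] - self.means[v.view_name]) / self.sds[v.view_name]
            names = tuple(f for f, k in zip(v.feature_names, keep) if k)
            out.append(FeatureMatrix(v.view_name, v.sample_ids, names, z))
        return MultiViewDataset(tuple(out), dataset.sample_ids, dataset.outcome)

    def fit_transform(self, dataset: MultiViewDataset) -> MultiViewDataset:
        return self.fit(dataset).transform(dataset)


def standardize(dataset: MultiViewDataset) -> tuple[MultiViewDataset, Standardizer]:
    """Standardize every view; returns the dataset and the fitted transform."""
    sz = Standardizer()
    return sz.fit_transform(dataset), sz
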