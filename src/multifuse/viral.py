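"""Viral strain encoders: binary mutation matrices and mutation-token embeddings.

A strain is summarized by its catalog of amino-acid mutation tokens
(``"S:N501Y"`` — gene, reference residue, position, alternate residue).
Two numeric encodings are supported:

* **binary** — one 0/1 column per distinct mutation (alignment-based,
  dimension = vocabulary size);
* **skip-gram** — mutations are treated as words and strains as sentences;
  a skip-gram model with negative sampling learns a dense vector per
  mutation, and a strain is embedded as the mean of its mutation vectors.
  Co-occurring (co-inherited) mutations receive nearby vectors, so strains
  from related clades land close together.

Strains with outlying mutation counts (outside Q1 − 1.5·IQR, Q3 + 1.5·IQR)
are removed before training; strain spaces are visualized by metric MDS on
the pairwise cosine dissimilarity.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from ._solvers import skipgram_train
from .data import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCatalog",
    "StrainEmbedding",
    "Projection2D",
    "read_catalog",
    "write_catalog",
    "binary_encode",
    "iqr_filter",
    "train_skipgram",
    "embed_new_strains",
    "cosine_dissimilarity",
    "mds_project",
]

_TOKEN_RE = re.compile(r"^[A-Za-z0-9_]+:[A-Za-z*][0-9]+[A-Za-z*\-]$")


def _token_position(token: str) -> tuple[str, int]:
    gene, rest = token.split(":", 1)
    return gene, int(re.search(r"[0-9]+", rest).group())


@dataclass(frozen=True)
class MutationCatalog:
    """Per-strain amino-acid mutation token lists with optional clade labels."""

    strains: tuple[str, ...]
    tokens_per_strain: tuple[tuple[str, ...], ...]
    clade_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain identifiers")
        if len(self.tokens_per_strain) != len(self.strains):
            raise ValueError("token lists do not match strain count")
        for sid, toks in zip(self.strains, self.tokens_per_strain):
            if len(set(toks)) != len(toks):
                raise ValueError(f"duplicate tokens within strain {sid!r}")
            for t in toks:
                if not _TOKEN_RE.match(t):
                    raise ValueError(f"malformed mutation token {t!r} in strain {sid!r}")
        if self.clade_labels is not None and len(self.clade_labels) != len(self.strains):
            raise ValueError("clade labels do not match strain count")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def token_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.tokens_per_strain])

    def vocabulary(self) -> list[str]:
        """Unique tokens, ordered by first appearance."""
        seen: dict[str, None] = {}
        for toks in self.tokens_per_strain:
            for t in toks:
                seen.setdefault(t, None)
        return list(seen)

    def subset(self, keep: np.ndarray) -> "MutationCatalog":
        keep = np.asarray(keep)
        idx = np.where(keep)[0] if keep.dtype == bool else keep
        return MutationCatalog(
            tuple(self.strains[i] for i in idx),
            tuple(self.tokens_per_strain[i] for i in idx),
            None if self.clade_labels is None
            else tuple(self.clade_labels[i] for i in idx))


def read_catalog(path: str | Path) -> MutationCatalog:
    """Read a catalog from TSV (``strain<TAB>tok1,tok2``) or JSON-lines."""
    path = Path(path)
    strains, tokens, clades = [], [], []
    has_clade = False
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.lstrip().startswith("{"):
                rec = json.loads(line)
                strains.append(str(rec["strain"]))
                tokens.append(tuple(rec["mutations"]))
                if "clade" in rec:
                    has_clade = True
                    clades.append(str(rec["clade"]))
            else:
                parts = line.split("\t")
                strains.append(parts[0])
                toks = parts[1] if len(parts) > 1 else ""
                tokens.append(tuple(t for t in toks.split(",") if t))
    return MutationCatalog(tuple(strains), tuple(tokens),
                           tuple(clades) if has_clade else None)


def write_catalog(catalog: MutationCatalog, path: str | Path,
                  fmt: str = "jsonl") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for i, (sid, toks) in enumerate(zip(catalog.strains,
                                            catalog.tokens_per_strain)):
            if fmt == "jsonl":
                rec = {"strain": sid, "mutations": list(toks)}
                if catalog.clade_labels is not None:
                    rec["clade"] = catalog.clade_labels[i]
                fh.write(json.dumps(rec) + "\n")
            else:
                fh.write(f"{sid}\t{','.join(toks)}\n")


def binary_encode(catalog: MutationCatalog) -> FeatureMatrix:
    """0/1 presence matrix, one column per distinct mutation token."""
    if catalog.n_strains == 0:
        raise ValueError("empty strain list")
    vocab = catalog.vocabulary()
    col = {t: j for j, t in enumerate(vocab)}
    values = np.zeros((catalog.n_strains, len(vocab)))
    for i, toks in enumerate(catalog.tokens_per_strain):
        for t in toks:
            values[i, col[t]] = 1.0
    return FeatureMatrix("viral_binary", catalog.strains, tuple(vocab), values)


def iqr_filter(catalog: MutationCatalog
               ) -> tuple[MutationCatalog, list[str]]:
    """Drop strains with outlying mutation counts (Tukey 1.5·IQR fences).

    Quartiles use linear interpolation (type 7).
    """
    if catalog.n_strains < 4:
        raise ValueError("need at least 4 strains for quartile fences")
    counts = catalog.token_counts()
    q1, q3 = np.percentile(counts, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (counts >= lo) & (counts <= hi)
    removed = [s for s, k in zip(catalog.strains, keep) if not k]
    if removed:
        logger.info("IQR filter removed %d/%d strains", len(removed),
                    catalog.n_strains)
    return catalog.subset(keep), removed


@dataclass
class StrainEmbedding:
    """Learned mutation-token vectors and derived strain mean-vectors."""

    token_vectors: np.ndarray  # vocab × d
    strain_vectors: np.ndarray  # n × d
    strain_ids: tuple[str, ...]
    vocab: tuple[str, ...]
    d: int
    window: int
    excluded_strains: tuple[str, ...] = ()

    def token_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocab)}

    def to_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix("viral_word2vec", self.strain_ids,
                             tuple(f"dim{i + 1}" for i in range(self.d)),
                             self.strain_vectors)


def _mean_vectors(catalog: MutationCatalog, vocab_index: dict[str, int],
                  token_vectors: np.ndarray
                  ) -> tuple[np.ndarray, list[str], list[str]]:
    vectors, kept, excluded = [], [], []
    n_oov = 0
    for sid, toks in zip(catalog.strains, catalog.tokens_per_strain):
        idx = [vocab_index[t] for t in toks if t in vocab_index]
        n_oov += len(toks) - len(idx)
        if not idx:
            excluded.append(sid)
            continue
        vectors.append(token_vectors[idx].mean(axis=0))
        kept.append(sid)
    if n_oov:
        logger.info("skipped %d out-of-vocabulary tokens", n_oov)
    if excluded:
        logger.warning("%d strains had no in-vocabulary tokens and were excluded",
                       len(excluded))
    return (np.array(vectors) if vectors else np.zeros((0, token_vectors.shape[1])),
            kept, excluded)


def train_skipgram(catalog: MutationCatalog, d: int = 300, window: int = 115,
                   epochs: int = 10, seed: int = 0, min_count: int = 1,
                   negatives: int = 5, lr: float = 0.025) -> StrainEmbedding:
    """Train mutation-token vectors by skip-gram with negative sampling.

    Sentences are per-strain token lists ordered by genomic coordinate
    (gene, then position); with ``window`` at least the longest sentence the
    ordering is immaterial.  Deterministic for a fixed seed (single worker).
    """
    freq: dict[str, int] = {}
    for toks in catalog.tokens_per_strain:
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    vocab = [t for t in catalog.vocabulary() if freq[t] >= min_count]
    if not vocab:
        raise ValueError("vocabulary empty after min-count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    sentences = []
    for toks in catalog.tokens_per_strain:
        ordered = sorted((t for t in toks if t in index), key=_token_position)
        sentences.append(np.array([index[t] for t in ordered], dtype=np.int64))
    flat = (np.concatenate([s for s in sentences if len(s)])
            if any(len(s) for s in sentences) else np.zeros(0, np.int64))
    offsets = np.zeros(len(sentences) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in sentences], out=offsets[1:])

    counts = np.array([freq[t] for t in vocab], dtype=float)
    weights = counts ** 0.75
    table_size = max(10_000, 10 * len(vocab))
    cum = np.cumsum(weights / weights.sum())
    neg_table = np.searchsorted(cum, (np.arange(table_size) + 0.5) / table_size
                                ).astype(np.int64)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((len(vocab), d)) - 0.5) / d
    w_out = np.zeros((len(vocab), d))
    skipgram_train(flat, offsets, w_in, w_out, window, negatives, neg_table,
                   epochs, lr, lr * 1e-4, seed % (2 ** 31 - 1))

    strain_vecs, kept, excluded = _mean_vectors(catalog, index, w_in)
    return StrainEmbedding(w_in, strain_vecs, tuple(kept), tuple(vocab), d,
                           window, tuple(excluded))


def embed_new_strains(embedding: StrainEmbedding, catalog: MutationCatalog
                      ) -> tuple[np.ndarray, list[str], list[str]]:
    """Mean-vector embedding of new strains in a trained token space.

    Returns (vectors, embedded strain ids, excluded strain ids); tokens
    absent from the training vocabulary are skipped with a logged count.
    """
    return _mean_vectors(catalog, embedding.token_index(),
                         embedding.token_vectors)


def cosine_dissimilarity(vectors: np.ndarray) -> np.ndarray:
    """Pairwise 1 − cosine similarity; symmetric with zero diagonal."""
    vectors = np.asarray(vectors, float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm row; cosine dissimilarity undefined")
    unit = vectors / norms[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2, 0.0, 2.0)


@dataclass
class Projection2D:
    """2-D MDS coordinates with the normalized stress of the fit."""

    coordinates: np.ndarray
    stress: float
    dissimilarity: np.ndarray

    def to_frame(self, ids=None) -> pd.DataFrame:
        n = self.coordinates.shape[0]
        ids = list(ids) if ids is not None else list(range(n))
        return pd.DataFrame({"strain_id": ids,
                             "x": self.coordinates[:, 0],
                             "y": self.coordinates[:, 1]})


def mds_project(D: np.ndarray, seed: int = 0, n_init: int = 4,
                max_iter: int = 1000, eps: float = 1e-13) -> Projection2D:
    """Metric MDS (stress majorization / SMACOF) of a precomputed dissimilarity."""
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    if D.shape[0] == 2:
        d = D[0, 1]
        coords = np.array([[-d / 2, 0.0], [d / 2, 0.0]])
        return Projection2D(coords, 0.0, D)
    coords, raw_stress = smacof(D, n_components=2, n_init=n_init,
                                max_iter=max_iter, eps=eps, random_state=seed,
                                normalized_stress=False)
    denom = (D ** 2).sum() / 2
    stress = float(np.sqrt(raw_stress / denom)) if denom > 0 else 0.0
    return Projection2D(coords, stress, D)
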