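"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators:

* :func:`gen_multiview` — several feature views sharing sparse latent
  canonical structure plus view-specific noise, with a binary outcome driven
  by the first latent factor.  This is the test bed for sparse CCA
  (parameter recovery) and cooperative learning (prediction power).
* :func:`gen_phylogeny` — clade-structured strain mutation catalogs: a
  uniform-depth clade tree whose branches each contribute novel mutation
  tokens, strains inheriting their root-to-leaf tokens with dropout plus
  private mutations, optional outlier and recombinant strains.
* :func:`gen_cohort` — a two-group patient table of Bernoulli comorbidities
  and continuous covariates for descriptive-table testing.

Every generator is a pure function of (scenario, seed): reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureMatrix, MultiViewDataset
from .viral import MutationCatalog

__all__ = [
    "MultiViewScenario",
    "PhylogenyScenario",
    "gen_multiview",
    "gen_phylogeny",
    "gen_catalog_with_vocab",
    "gen_cohort",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GENES = ("S", "N", "E", "M", "ORF1a", "ORF1b", "ORF3a", "ORF8")


@dataclass(frozen=True)
class MultiViewScenario:
    """Latent-factor scenario for multi-view generation.

    ``snr`` scales the shared signal relative to unit-variance noise;
    ``outcome_strength`` is the logistic slope of the outcome on the first
    latent factor.
    """

    n: int = 200
    p: tuple[int, ...] = (50, 50)
    K: int = 1
    sparsity: int = 5
    snr: float = 1.0
    outcome_strength: float = 2.0
    binary_views: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K > min(self.p):
            raise ValueError("K exceeds the smallest view dimension")
        if self.sparsity > min(self.p):
            raise ValueError("sparsity exceeds the smallest view dimension")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def gen_multiview(scenario: MultiViewScenario = MultiViewScenario()
                  ) -> tuple[MultiViewDataset, dict]:
    """Generate aligned views X_m = snr·S·W_mᵀ + noise and a latent-driven outcome.

    Returns the dataset and a truth dict with the latent scores ``S`` and
    per-view sparse loading matrices ``W`` (unit-norm columns) for recovery
    scoring.
    """
    rng = np.random.default_rng(scenario.seed)
    n, K = scenario.n, scenario.K
    S = rng.standard_normal((n, K))
    ids = tuple(f"s{i:05d}" for i in range(n))
    views, loadings = [], []
    for m, p in enumerate(scenario.p):
        W = np.zeros((p, K))
        for k in range(K):
            support = rng.choice(p, size=scenario.sparsity, replace=False)
            w = rng.standard_normal(scenario.sparsity)
            W[support, k] = w / np.linalg.norm(w)
        X = scenario.snr * S @ W.T + rng.standard_normal((n, p))
        if m in scenario.binary_views:
            X = (X > 0).astype(float)
        loadings.append(W)
        views.append(FeatureMatrix(
            f"view{m + 1}", ids, tuple(f"v{m + 1}_f{j:03d}" for j in range(p)), X))
    logit = scenario.outcome_strength * S[:, 0]
    prob = 1 / (1 + np.exp(-logit))
    y = (rng.random(n) < prob).astype(int)
    dataset = MultiViewDataset(tuple(views), ids, y)
    return dataset, {"S": S, "W": loadings, "prob": prob}


@dataclass(frozen=True)
class PhylogenyScenario:
    """Clade-tree scenario for strain mutation catalogs.

    Every root-to-leaf path has exactly ``tree_depth`` branches, each adding
    ``mutations_per_branch`` novel tokens, so a typical strain carries about
    ``tree_depth · mutations_per_branch · (1 − dropout) + private_rate``
    mutations — sized to echo the low-tens mutation counts of real
    SARS-CoV-2 catalogs.
    """

    n_clades: int = 6
    tree_depth: int = 4
    mutations_per_branch: int = 6
    dropout: float = 0.05
    private_rate: float = 2.0
    n_strains_per_clade: int = 40
    outlier_rate: float = 0.0
    outlier_size: int = 80
    recombinant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.dropout, self.outlier_rate, self.recombinant_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_clades < 1 or self.tree_depth < 1:
            raise ValueError("empty tree")


class _TokenFactory:
    """Unique, syntactically valid mutation tokens (positions never repeat)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.pos = 0

    def new(self) -> str:
        self.pos += 1
        gene = _GENES[self.rng.integers(len(_GENES))]
        ref, alt = self.rng.choice(list(_AA), size=2)
        return f"{gene}:{ref}{self.pos}{alt}"


def _build_clade_paths(n_clades: int, depth: int, mpb: int,
                       rng: np.random.Generator,
                       factory: _TokenFactory) -> list[list[frozenset]]:
    """Per-clade list of per-level branch token sets (uniform depth).

    Clades are split recursively into balanced halves (random membership);
    once a branch holds a single clade it continues as a unary chain, so
    every path has exactly ``depth`` branch segments, sibling clades share
    exactly their common ancestors' tokens, and all clades are separated
    provided ``n_clades <= 2**(depth - 1)``.
    """
    if n_clades > 2 ** (depth - 1):
        raise ValueError(
            f"tree_depth={depth} cannot separate {n_clades} clades; "
            f"need n_clades <= 2**(tree_depth - 1)")
    paths: list[list[frozenset]] = [[] for _ in range(n_clades)]

    def grow(clades: list[int], level: int) -> None:
        if level == depth:
            return
        branch = frozenset(factory.new() for _ in range(mpb))
        for c in clades:
            paths[c].append(branch)
        if len(clades) == 1:
            grow(clades, level + 1)
            return
        cut = (len(clades) + 1) // 2
        order = list(rng.permutation(clades))
        grow(order[:cut], level + 1)
        grow(order[cut:], level + 1)

    grow(list(range(n_clades)), 0)
    return paths


def gen_phylogeny(scenario: PhylogenyScenario = PhylogenyScenario()
                  ) -> tuple[MutationCatalog, dict]:
    """Generate a clade-structured mutation catalog.

    Returns the catalog (with clade labels) and a truth dict containing the
    per-clade inherited token sets and the identifiers of planted outlier
    and recombinant strains.
    """
    rng = np.random.default_rng(scenario.seed)
    factory = _TokenFactory(rng)
    paths = _build_clade_paths(scenario.n_clades, scenario.tree_depth,
                               scenario.mutations_per_branch, rng, factory)
    clade_tokens = [frozenset().union(*p) if p else frozenset() for p in paths]

    strains, tokens, clades = [], [], []
    outliers, recombinants = [], []
    idx = 0
    for c in range(scenario.n_clades):
        inherited = sorted(clade_tokens[c])
        for _ in range(scenario.n_strains_per_clade):
            sid = f"strain{idx:05d}"
            idx += 1
            if scenario.recombinant_rate and rng.random() < scenario.recombinant_rate:
                other = int(rng.integers(scenario.n_clades))
                base = sorted(clade_tokens[c] | clade_tokens[other])
                recombinants.append(sid)
            else:
                base = inherited
            kept = [t for t in base if rng.random() >= scenario.dropout]
            n_private = int(rng.poisson(scenario.private_rate))
            private = [factory.new() for _ in range(n_private)]
            toks = kept + private
            if scenario.outlier_rate and rng.random() < scenario.outlier_rate:
                toks = toks + [factory.new() for _ in range(scenario.outlier_size)]
                outliers.append(sid)
            strains.append(sid)
            tokens.append(tuple(toks))
            clades.append(f"clade{c + 1}")
    catalog = MutationCatalog(tuple(strains), tuple(tokens), tuple(clades))
    truth = {"clade_tokens": clade_tokens, "paths": paths,
             "outliers": outliers, "recombinants": recombinants}
    return catalog, truth


def gen_catalog_with_vocab(n_strains: int = 105, vocab_size: int = 439,
                           mean_tokens: float = 22.0, seed: int = 0
                           ) -> MutationCatalog:
    """Catalog with an exactly known vocabulary size.

    Strain token counts are Poisson around ``mean_tokens``; tokens are drawn
    from a fixed pool and every pool token is guaranteed to appear in at
    least one strain, so the binary encoding has exactly ``vocab_size``
    columns.
    """
    rng = np.random.default_rng(seed)
    factory = _TokenFactory(rng)
    pool = [factory.new() for _ in range(vocab_size)]
    token_sets = []
    for _ in range(n_strains):
        k = min(vocab_size, max(1, int(rng.poisson(mean_tokens))))
        token_sets.append(set(rng.choice(vocab_size, size=k, replace=False)))
    used = set().union(*token_sets)
    for j in range(vocab_size):
        if j not in used:
            token_sets[int(rng.integers(n_strains))].add(j)
    return MutationCatalog(
        tuple(f"strain{i:05d}" for i in range(n_strains)),
        tuple(tuple(pool[j] for j in sorted(s)) for s in token_sets))


def gen_cohort(n: int = 149,
               prevalences: dict[str, tuple[float, float]] | None = None,
               continuous_specs: dict[str, tuple[float, float, float, float]]
               | None = None,
               group_ratio: float = 63 / 149, seed: int = 0) -> pd.DataFrame:
    """Two-group cohort table of binary comorbidities and continuous covariates.

    ``prevalences[var] = (rate_group0, rate_group1)`` for Bernoulli
    variables; ``continuous_specs[var] = (mean0, sd0, mean1, sd1)`` for
    normal variables.  ``group_ratio`` is the fraction in group 1 (the
    default mirrors a cohort with 63 of 149 in the positive group).
    """
    rng = np.random.default_rng(seed)
    prevalences = prevalences if prevalences is not None else {
        "hypertension": (0.40, 0.60), "diabetes": (0.26, 0.35)}
    continuous_specs = continuous_specs if continuous_specs is not None else {
        "age": (53.1, 15.6, 63.9, 15.0)}
    for var, (r0, r1) in prevalences.items():
        if not (0 <= r0 <= 1 and 0 <= r1 <= 1):
            raise ValueError(f"prevalence out of [0,1] for {var!r}")
    n1 = int(round(n * group_ratio))
    group = np.zeros(n, dtype=int)
    group[rng.choice(n, size=n1, replace=False)] = 1
    data = {"group": group}
    for var, (r0, r1) in prevalences.items():
        rates = np.where(group == 1, r1, r0)
        data[var] = (rng.random(n) < rates).astype(int)
    for var, (m0, s0, m1, s1) in continuous_specs.items():
        mu = np.where(group == 1, m1, m0)
        sd = np.where(group == 1, s1, s0)
        data[var] = rng.standard_normal(n) * sd + mu
    df = pd.DataFrame(data)
    df.insert(0, "sample_id", [f"p{i:04d}" for i in range(n)])
    return df
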