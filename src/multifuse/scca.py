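"""Sparse canonical correlation analysis via penalized matrix decomposition.

Two-view sparse CCA finds unit-norm, L1-bounded weight vectors u, v
maximizing the cross-covariance u'X'Zv by alternating soft-thresholded
power iterations on the cross-product matrix M = X'Z; further components
come from rank-one deflation of M.  The multi-view extension maximizes the
sum of pairwise cross-covariances by block coordinate ascent.  Sparsity
parameters are chosen by a permutation scheme: the observed canonical
correlation is compared, on the Fisher z scale, with its distribution under
row permutations that break the across-view pairing, and the bound with the
largest z-statistic wins.

Two covariance treatments are available.  The default (``whiten=False``)
treats within-view covariances as identity, the classical penalized matrix
decomposition simplification that keeps the L1 constraint acting on the
original features.  ``whiten=True`` whitens each view first (requires more
samples than features per view); with non-binding bounds this mode is
exactly classical generalized-eigenvalue CCA and serves as the bridge to
the textbook method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureMatrix, MultiViewDataset

logger = logging.getLogger(__name__)

__all__ = [
    "soft_threshold",
    "l1_constrained_unit_vector",
    "SparseCCA",
    "SparseCCAResults",
    "MultiCCA",
    "MultiCCAResults",
    "PermutationTuning",
    "sparse_cca",
    "cca_permute",
    "multi_cca",
    "multi_cca_permute",
]

_ATANH_CLIP = 1.0 - 1e-12


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(a)·max(|a|−delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def l1_constrained_unit_vector(a: np.ndarray, c: float, tol: float = 1e-10) -> np.ndarray:
    """argmax of w·a subject to ‖w‖₂ ≤ 1 and ‖w‖₁ ≤ c.

    The maximizer is S(a, Δ)/‖S(a, Δ)‖₂ for the smallest Δ ≥ 0 making the
    L1 constraint feasible; Δ is located by bisection on [0, max|a|].
    """
    a = np.asarray(a, dtype=float)
    if not np.any(a):
        raise ValueError("zero input vector")
    if c < 1:
        raise ValueError("c must be at least 1 (unit vectors have L1 norm >= 1)")
    w = a / np.linalg.norm(a)
    if np.abs(w).sum() <= c:
        return w
    lo, hi = 0.0, float(np.abs(a).max())
    while hi - lo > tol:
        mid = (lo + hi) / 2
        s = soft_threshold(a, mid)
        norm = np.linalg.norm(s)
        if norm == 0 or np.abs(s).sum() / norm > c:
            lo = mid
        else:
            hi = mid
    s = soft_threshold(a, hi)
    norm = np.linalg.norm(s)
    if norm > 0 and np.abs(s).sum() / norm <= c + 1e-6:
        return s / norm
    # exact ties in |a| at the saturation boundary: soft-thresholding cannot
    # break the tie, so place equal weight on the first k = floor(c^2) tied
    # coordinates (feasible, deterministic; a measure-zero case)
    tied = np.flatnonzero(np.abs(a) >= hi - tol)
    k = max(1, min(len(tied), int(c ** 2)))
    w = np.zeros_like(a)
    w[tied[:k]] = np.sign(a[tied[:k]]) / np.sqrt(k)
    return w


def _leading_right_singular(M: np.ndarray) -> np.ndarray:
    """Deterministic leading right singular vector (sign-fixed)."""
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    j = int(np.argmax(np.abs(v)))
    return v if v[j] >= 0 else -v


def _sign_fix(w: np.ndarray) -> tuple[np.ndarray, float]:
    j = int(np.argmax(np.abs(w)))
    return (w, 1.0) if w[j] >= 0 else (-w, -1.0)


def _whitener(X: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of X'X (requires full column rank)."""
    S = X.T @ X
    vals, vecs = np.linalg.eigh(S)
    if vals.min() <= 1e-10 * vals.max():
        raise ValueError("view is rank-deficient; whitening requires n > p "
                         "and linearly independent columns")
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def _rank1_pmd(M: np.ndarray, cx: float, cz: float,
               max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Alternating maximization of u'Mv under L2/L1 constraints."""
    v = _leading_right_singular(M)
    u = np.zeros(M.shape[0])
    for _ in range(max_iter):
        u_new = l1_constrained_unit_vector(M @ v, cx)
        v_new = l1_constrained_unit_vector(M.T @ u_new, cz)
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            break
    return u, v


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SparseCCAResults:
    """Canonical vectors, correlations and diagnostics from :class:`SparseCCA`."""

    u: np.ndarray  # p × K
    v: np.ndarray  # q × K
    correlations: np.ndarray  # K
    l1_bounds: tuple[float, float]  # fractions of sqrt(dim)
    nonzero_counts: list[tuple[int, int]]
    K: int
    feature_names: tuple[tuple[str, ...], tuple[str, ...]] | None = None

    def summary(self) -> str:
        lines = ["Sparse CCA results",
                 f"  components: {self.K}",
                 f"  L1 bounds (fractions): {self.l1_bounds[0]:.3g} / {self.l1_bounds[1]:.3g}"]
        for k in range(self.K):
            nx, nz = self.nonzero_counts[k]
            lines.append(f"  comp {k + 1}: corr={self.correlations[k]:+.4f} "
                         f"nonzero X={nx} Z={nz}")
        return "\n".join(lines)

    def loadings_frame(self) -> pd.DataFrame:
        """Long-format (view, feature, component, coefficient) table."""
        rows = []
        names_x = (self.feature_names[0] if self.feature_names
                   else [f"x{i}" for i in range(self.u.shape[0])])
        names_z = (self.feature_names[1] if self.feature_names
                   else [f"z{i}" for i in range(self.v.shape[0])])
        for k in range(self.K):
            rows += [("X", f, k + 1, self.u[i, k]) for i, f in enumerate(names_x)]
            rows += [("Z", f, k + 1, self.v[i, k]) for i, f in enumerate(names_z)]
        return pd.DataFrame(rows, columns=["view", "feature", "component", "coefficient"])


class SparseCCA:
    """Two-view sparse CCA model (fit by penalized matrix decomposition).

    Parameters
    ----------
    X, Z : array or FeatureMatrix
        Standardized, row-aligned views of shapes n×p and n×q.
    whiten : bool
        Whiten each view before decomposition (see module docstring).
    """

    def __init__(self, X, Z, whiten: bool = False):
        self._names = None
        if isinstance(X, FeatureMatrix) and isinstance(Z, FeatureMatrix):
            self._names = (X.feature_names, Z.feature_names)
        self.X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        self.Z = Z.values if isinstance(Z, FeatureMatrix) else np.asarray(Z, float)
        if self.X.shape[0] != self.Z.shape[0]:
            raise ValueError("X and Z must have the same number of rows")
        self.whiten = whiten
        if whiten:
            self._Wx = _whitener(self.X)
            self._Wz = _whitener(self.Z)
            self._Xw = self.X @ self._Wx
            self._Zw = self.Z @ self._Wz
        else:
            self._Xw, self._Zw = self.X, self.Z

    @classmethod
    def from_dataset(cls, dataset: MultiViewDataset, x: str, z: str,
                     whiten: bool = False) -> "SparseCCA":
        return cls(dataset.view(x), dataset.view(z), whiten=whiten)

    def fit(self, l1_x: float = 0.3, l1_z: float = 0.3, K: int = 1,
            max_iter: int = 50, tol: float = 1e-6) -> SparseCCAResults:
        if not (0 < l1_x <= 1 and 0 < l1_z <= 1):
            raise ValueError("L1 bounds are fractions in (0, 1]")
        p, q = self._Xw.shape[1], self._Zw.shape[1]
        if K > min(p, q):
            raise ValueError(f"K={K} exceeds min(p, q)={min(p, q)}")
        cx = max(1.0, l1_x * np.sqrt(p))
        cz = max(1.0, l1_z * np.sqrt(q))
        M = self._Xw.T @ self._Zw
        U = np.zeros((p, K))
        V = np.zeros((q, K))
        corrs = np.zeros(K)
        nnz = []
        for k in range(K):
            u, v = _rank1_pmd(M, cx, cz, max_iter, tol)
            d = float(u @ M @ v)
            M = M - d * np.outer(u, v)
            u, _ = _sign_fix(u)
            v, _ = _sign_fix(v)
            nnz.append((int(np.count_nonzero(u)), int(np.count_nonzero(v))))
            if self.whiten:
                u_raw = self._Wx @ u
                v_raw = self._Wz @ v
                corrs[k] = _safe_corr(self.X @ u_raw, self.Z @ v_raw)
                U[:, k] = u_raw / np.linalg.norm(u_raw)
                V[:, k] = v_raw / np.linalg.norm(v_raw)
            else:
                corrs[k] = _safe_corr(self.X @ u, self.Z @ v)
                U[:, k], V[:, k] = u, v
        return SparseCCAResults(U, V, corrs, (l1_x, l1_z), nnz, K,
                                feature_names=self._names)

    def permute(self, grid=None, n_permutations: int = 100,
                seed: int = 0, **fit_kw) -> "PermutationTuning":
        """Permutation-based selection of the L1 bounds (see module docstring)."""
        return cca_permute(self.X, self.Z, grid=grid,
                           n_permutations=n_permutations, seed=seed,
                           whiten=self.whiten, **fit_kw)


def sparse_cca(X, Z, l1_x: float = 0.3, l1_z: float = 0.3, K: int = 1,
               max_iter: int = 50, tol: float = 1e-6,
               whiten: bool = False) -> SparseCCAResults:
    """Functional wrapper around :class:`SparseCCA`."""
    return SparseCCA(X, Z, whiten=whiten).fit(l1_x, l1_z, K, max_iter, tol)


@dataclass
class PermutationTuning:
    """Outcome of permutation-based sparsity selection."""

    grid: list
    zstats: np.ndarray
    correlations: np.ndarray  # observed statistic per grid point
    pvalue: float
    best: object
    best_index: int
    n_permutations: int
    seed: int
    perm_stats: np.ndarray = field(repr=False, default=None)  # best grid point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": [str(g) for g in self.grid],
            "zstat": self.zstats,
            "statistic": self.correlations,
        })

    def summary(self) -> str:
        return (f"Permutation tuning: best={self.best} "
                f"zstat={self.zstats[self.best_index]:.3f} "
                f"p={self.pvalue:.4g} ({self.n_permutations} permutations)")


_DEFAULT_GRID = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]


def _grid_sort_key(g):
    g = np.atleast_1d(np.asarray(g, float))
    return (float(g.sum()), *map(float, g))


def _zstats_from(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Fisher-z standardized observed statistics; perm is n_perm × n_grid."""
    z_obs = np.arctanh(np.clip(obs, -_ATANH_CLIP, _ATANH_CLIP))
    z_perm = np.arctanh(np.clip(perm, -_ATANH_CLIP, _ATANH_CLIP))
    mu = z_perm.mean(axis=0)
    sd = z_perm.std(axis=0, ddof=1)
    out = np.zeros_like(z_obs)
    ok = sd > 0
    if not ok.all():
        warnings.warn("degenerate permutation spread; z-stat reported as 0")
    out[ok] = (z_obs[ok] - mu[ok]) / sd[ok]
    return out


def cca_permute(X, Z, grid=None, n_permutations: int = 100, seed: int = 0,
                whiten: bool = False, K: int = 1, max_iter: int = 50,
                tol: float = 1e-6) -> PermutationTuning:
    """Select pairwise L1 bounds by the permutation z-statistic.

    The same row permutations of Z are reused across grid points; the
    p-value is reported at the winning grid point as
    ``(1 + #{r_perm >= r_obs}) / (1 + n_permutations)``.
    """
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    Z = Z.values if isinstance(Z, FeatureMatrix) else np.asarray(Z, float)
    if grid is None:
        grid = _DEFAULT_GRID
    grid = [(float(g), float(g)) if np.isscalar(g) else (float(g[0]), float(g[1]))
            for g in grid]
    if not grid:
        raise ValueError("empty grid")
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perms = [rng.permutation(n) for _ in range(n_permutations)]

    def first_corr(Xa, Za, fx, fz):
        res = SparseCCA(Xa, Za, whiten=whiten).fit(fx, fz, K=1,
                                                   max_iter=max_iter, tol=tol)
        return abs(res.correlations[0])

    obs = np.array([first_corr(X, Z, fx, fz) for fx, fz in grid])
    perm = np.array([[first_corr(X, Z[pi], fx, fz) for fx, fz in grid]
                     for pi in perms])
    zstats = _zstats_from(obs, perm)
    order = sorted(range(len(grid)),
                   key=lambda i: (-zstats[i], _grid_sort_key(grid[i])))
    best_i = order[0]
    pvalue = (1 + int((perm[:, best_i] >= obs[best_i]).sum())) / (1 + n_permutations)
    return PermutationTuning(grid, zstats, obs, pvalue, grid[best_i], best_i,
                             n_permutations, seed, perm_stats=perm[:, best_i])


@dataclass
class MultiCCAResults:
    """Weights and diagnostics for multi-view sparse CCA."""

    weights: list[np.ndarray]  # p_i × K each
    penalties: list[float]  # absolute L1 bounds c_i
    objective: float
    objective_trace: list[float]
    correlations: np.ndarray  # K × n_pairs pairwise canonical correlations
    K: int
    view_names: tuple[str, ...] | None = None

    def pairwise_frame(self, component: int = 1) -> pd.DataFrame:
        names = self.view_names or tuple(f"view{i + 1}" for i in range(len(self.weights)))
        m = len(self.weights)
        out = pd.DataFrame(np.eye(m), index=names, columns=names)
        idx = 0
        for i in range(m):
            for j in range(i + 1, m):
                r = self.correlations[component - 1, idx]
                out.iloc[i, j] = out.iloc[j, i] = r
                idx += 1
        return out

    def summary(self) -> str:
        pen = ", ".join(f"{c:.3f}" for c in self.penalties)
        return (f"Multi-view sparse CCA: {len(self.weights)} views, K={self.K}, "
                f"penalties=({pen}), objective={self.objective:.4f}")


class MultiCCA:
    """Sparse CCA over three or more views by block coordinate ascent."""

    def __init__(self, views, penalties=None):
        if isinstance(views, MultiViewDataset):
            self._names = views.view_names
            self.views = views.matrices()
        else:
            self._names = None
            self.views = [v.values if isinstance(v, FeatureMatrix)
                          else np.asarray(v, float) for v in views]
        if len(self.views) < 3:
            raise ValueError("multi-view CCA needs >= 3 views; use SparseCCA for two")
        n = self.views[0].shape[0]
        if any(v.shape[0] != n for v in self.views):
            raise ValueError("views must be row-aligned")
        self.penalties = penalties

    def _resolve_penalties(self, penalties):
        if penalties is None:
            penalties = self.penalties
        if penalties is None:
            penalties = [0.5 * np.sqrt(v.shape[1]) for v in self.views]
        pens = []
        for c, v in zip(penalties, self.views):
            c = float(c)
            if not (1.0 <= c <= np.sqrt(v.shape[1]) + 1e-9):
                raise ValueError(f"penalty {c} outside [1, sqrt(p)] for p={v.shape[1]}")
            pens.append(c)
        return pens

    def fit(self, penalties=None, K: int = 1, max_iter: int = 50,
            tol: float = 1e-6) -> MultiCCAResults:
        pens = self._resolve_penalties(penalties)
        m = len(self.views)
        cross = {(i, j): self.views[i].T @ self.views[j]
                 for i in range(m) for j in range(i + 1, m)}
        Ws = [np.zeros((v.shape[1], K)) for v in self.views]
        corrs = np.zeros((K, m * (m - 1) // 2))
        trace: list[float] = []
        final_obj = 0.0
        for k in range(K):
            # project the SVD initializer onto the constraint set so the
            # ascent trace starts from a feasible point (keeps it monotone)
            ws = [l1_constrained_unit_vector(_leading_right_singular(v), c)
                  for v, c in zip(self.views, pens)]

            def objective():
                return sum(float(ws[i] @ cross[(i, j)] @ ws[j])
                           for i in range(m) for j in range(i + 1, m))

            prev = objective()
            trace.append(prev)
            for _ in range(max_iter):
                for i in range(m):
                    a = np.zeros(self.views[i].shape[1])
                    for j in range(m):
                        if j == i:
                            continue
                        a += cross[(i, j)] @ ws[j] if i < j else cross[(j, i)].T @ ws[j]
                    if np.any(a):
                        ws[i] = l1_constrained_unit_vector(a, pens[i])
                cur = objective()
                trace.append(cur)
                if abs(cur - prev) < tol:
                    break
                prev = cur
            final_obj = trace[-1]
            idx = 0
            for i in range(m):
                for j in range(i + 1, m):
                    corrs[k, idx] = _safe_corr(self.views[i] @ ws[i],
                                               self.views[j] @ ws[j])
                    d = float(ws[i] @ cross[(i, j)] @ ws[j])
                    cross[(i, j)] = cross[(i, j)] - d * np.outer(ws[i], ws[j])
                    idx += 1
            for i in range(m):
                Ws[i][:, k], _ = _sign_fix(ws[i])
        return MultiCCAResults(Ws, pens, final_obj, trace, corrs, K,
                               view_names=self._names)

    def permute(self, grid=None, n_permutations: int = 100,
                seed: int = 0) -> PermutationTuning:
        return multi_cca_permute(self.views, grid=grid,
                                 n_permutations=n_permutations, seed=seed,
                                 view_names=self._names)


def multi_cca(views, penalties=None, K: int = 1, max_iter: int = 50,
              tol: float = 1e-6) -> MultiCCAResults:
    """Functional wrapper around :class:`MultiCCA`."""
    return MultiCCA(views, penalties).fit(penalties, K, max_iter, tol)


def multi_cca_permute(views, grid=None, n_permutations: int = 100,
                      seed: int = 0, view_names=None) -> PermutationTuning:
    """Permutation selection of multi-view penalties.

    The statistic is the sum over view pairs of Fisher-z transformed
    canonical correlations; under permutation each view's rows are shuffled
    independently with the first view held fixed.
    """
    if isinstance(views, MultiViewDataset):
        view_names = views.view_names
        views = views.matrices()
    views = [v.values if isinstance(v, FeatureMatrix) else np.asarray(v, float)
             for v in views]
    m = len(views)
    if grid is None:
        grid = [[f * np.sqrt(v.shape[1]) for v in views]
                for f in (0.1, 0.3, 0.5, 0.7)]
        grid = [[max(1.0, c) for c in g] for g in grid]
    grid = [list(map(float, g)) for g in grid]
    if not grid:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    n = views[0].shape[0]
    perms = [[np.arange(n)] + [rng.permutation(n) for _ in range(m - 1)]
             for _ in range(n_permutations)]

    def statistic(vs, pens):
        res = MultiCCA(vs).fit(pens, K=1)
        r = np.clip(res.correlations[0], -_ATANH_CLIP, _ATANH_CLIP)
        return float(np.arctanh(np.abs(r)).sum())

    obs = np.array([statistic(views, g) for g in grid])
    perm = np.array([[statistic([v[pi] for v, pi in zip(views, ps)], g)
                      for g in grid] for ps in perms])
    # the summed-z statistic is already on the z scale; standardize directly
    mu, sd = perm.mean(axis=0), perm.std(axis=0, ddof=1)
    zstats = np.zeros(len(grid))
    ok = sd > 0
    if not ok.all():
        warnings.warn("degenerate permutation spread; z-stat reported as 0")
    zstats[ok] = (obs[ok] - mu[ok]) / sd[ok]
    order = sorted(range(len(grid)),
                   key=lambda i: (-zstats[i], _grid_sort_key(grid[i])))
    best_i = order[0]
    pvalue = (1 + int((perm[:, best_i] >= obs[best_i]).sum())) / (1 + n_permutations)
    return PermutationTuning(grid, zstats, obs, pvalue, grid[best_i], best_i,
                             n_permutations, seed, perm_stats=perm[:, best_i])
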