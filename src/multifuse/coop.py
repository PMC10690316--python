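"""Cooperative learning: multi-view penalized regression with an agreement penalty.

The model predicts an outcome from M row-aligned views X_1 … X_M while
encouraging the per-view linear predictions to agree.  For the gaussian
family the objective is

    (1/2n) ‖y_c − Σ_m X_m β_m‖²
    + (ρ/2n) Σ_{m<m'} ‖X_m β_m − X_{m'} β_{m'}‖²
    + λ ( α‖β‖₁ + (1−α)/2 ‖β‖² ),

where y_c is the centered outcome.  ρ = 0 is early fusion (a single
elastic net on the concatenated features); growing ρ pushes the per-view
predictions together, approaching late-fusion-like behavior.  The quadratic
agreement term is folded into an augmented least-squares system — one row
block per unordered view pair — so a standard elastic-net coordinate
descent solves the whole continuum.  Binomial outcomes are fitted by
penalized IRLS in which every weighted working-response step reuses the
same augmentation, i.e. the agreement penalty acts on the linear
predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solvers import enet_coordinate_descent
from .data import FeatureMatrix, MultiViewDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CooperativeNet",
    "CoopResults",
    "LateFusionResults",
    "build_augmented_design",
    "fit_coop",
    "fit_late_fusion",
    "predict",
]

_ALPHA_FLOOR = 1e-3  # path construction when alpha=0 (ridge has no finite lambda_max)


def _as_matrices(views) -> list[np.ndarray]:
    if isinstance(views, MultiViewDataset):
        return views.matrices()
    return [v.values if isinstance(v, FeatureMatrix) else np.asarray(v, float)
            for v in views]


def build_augmented_design(views, y: np.ndarray, rho: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Augmented (design, response) whose least squares realizes the agreement penalty.

    Top block: [X_1 … X_M] with response y − ȳ; then one block per
    unordered view pair (m, m') holding −√ρ·X_m and +√ρ·X_{m'} with
    response 0.
    """
    Xs = _as_matrices(views)
    if rho < 0:
        raise ValueError("rho must be non-negative")
    n = Xs[0].shape[0]
    if any(X.shape[0] != n for X in Xs) or len(y) != n:
        raise ValueError("views and outcome must be row-aligned")
    ps = [X.shape[1] for X in Xs]
    M = len(Xs)
    sr = np.sqrt(rho)
    n_pairs = M * (M - 1) // 2
    A = np.zeros((n * (1 + n_pairs), sum(ps)))
    A[:n] = np.hstack(Xs)
    offsets = np.concatenate([[0], np.cumsum(ps)])
    block = 1
    for m in range(M):
        for m2 in range(m + 1, M):
            rows = slice(block * n, (block + 1) * n)
            A[rows, offsets[m]:offsets[m + 1]] = -sr * Xs[m]
            A[rows, offsets[m2]:offsets[m2 + 1]] = sr * Xs[m2]
            block += 1
    y = np.asarray(y, float)
    b = np.zeros(A.shape[0])
    b[:n] = y - y.mean()
    return A, b


def _lambda_path(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1 + np.tanh(0.5 * x))


@dataclass
class CoopResults:
    """Fitted cooperative-learning path.

    ``coefs`` is P × L (features × λ values) on the standardized-feature
    scale; per-view blocks are recovered through ``view_slices``.
    """

    coefs: np.ndarray
    intercepts: np.ndarray
    lambda_path: np.ndarray
    rho: float
    alpha: float
    family: str
    view_slices: list[slice]
    view_names: tuple[str, ...] | None = None
    feature_names: list[tuple[str, ...]] | None = None
    selected_lambda: float | None = None

    def _lambda_index(self, lam: float | None) -> int:
        if lam is None:
            lam = self.selected_lambda
        if lam is None:
            raise ValueError("no lambda selected; pass lam explicitly")
        return int(np.argmin(np.abs(self.lambda_path - lam)))

    def coefficients(self, lam: float | None = None) -> list[np.ndarray]:
        """Per-view coefficient blocks at (the nearest path value to) ``lam``."""
        i = self._lambda_index(lam)
        return [self.coefs[s, i] for s in self.view_slices]

    def intercept(self, lam: float | None = None) -> float:
        return float(self.intercepts[self._lambda_index(lam)])

    def predict(self, views, lam: float | None = None) -> np.ndarray:
        Xs = _as_matrices(views)
        i = self._lambda_index(lam)
        eta = self.intercepts[i] + np.hstack(Xs) @ self.coefs[:, i]
        return _sigmoid(eta) if self.family == "binomial" else eta

    def nonzero_counts(self, lam: float | None = None) -> list[int]:
        i = self._lambda_index(lam)
        return [int(np.count_nonzero(self.coefs[s, i])) for s in self.view_slices]

    def coefficients_frame(self, lam: float | None = None) -> pd.DataFrame:
        i = self._lambda_index(lam)
        rows = []
        for v, s in enumerate(self.view_slices):
            name = self.view_names[v] if self.view_names else f"view{v + 1}"
            feats = (self.feature_names[v] if self.feature_names
                     else [f"f{j}" for j in range(s.stop - s.start)])
            for f, c in zip(feats, self.coefs[s, i]):
                rows.append((name, f, c))
        return pd.DataFrame(rows, columns=["view", "feature", "coefficient"])

    def summary(self, lam: float | None = None) -> str:
        i = self._lambda_index(lam) if (lam or self.selected_lambda) else len(
            self.lambda_path) - 1
        nnz = [int(np.count_nonzero(self.coefs[s, i])) for s in self.view_slices]
        return ("Cooperative learning fit\n"
                f"  family={self.family} rho={self.rho} alpha={self.alpha}\n"
                f"  lambda={self.lambda_path[i]:.4g} "
                f"nonzero per view={nnz} intercept={self.intercepts[i]:+.4f}")


class CooperativeNet:
    """Cooperative-learning model over row-aligned views.

    Parameters
    ----------
    views : MultiViewDataset or list of matrices
        Standardized feature blocks (columns mean 0, unit variance).
    y : array
        Outcome; binary 0/1 for ``family='binomial'``.
    """

    def __init__(self, views, y=None, family: str = "gaussian"):
        if isinstance(views, MultiViewDataset):
            self._names = views.view_names
            self._features = [v.feature_names for v in views.views]
            if y is None:
                y = views.outcome
            views = views.matrices()
        else:
            self._names = None
            self._features = None
            views = _as_matrices(views)
        if y is None:
            raise ValueError("outcome y is required")
        self.views = views
        self.y = np.asarray(y, float)
        if family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {family!r}")
        if family == "binomial" and not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("binomial family requires binary 0/1 outcome")
        self.family = family
        ps = [X.shape[1] for X in views]
        off = np.concatenate([[0], np.cumsum(ps)])
        self.view_slices = [slice(int(off[i]), int(off[i + 1]))
                            for i in range(len(views))]

    # -- gaussian -----------------------------------------------------------
    def _fit_gaussian(self, rho, alpha, lambda_path, n_lambda, min_ratio,
                      max_iter, tol):
        A, b = build_augmented_design(self.views, self.y, rho)
        n0 = self.views[0].shape[0]
        if lambda_path is None:
            a_eff = max(alpha, _ALPHA_FLOOR)
            # tiny inflation keeps the path head exactly sparse despite rounding
            lam_max = np.abs(A.T @ b).max() / (n0 * a_eff) * (1 + 1e-8)
            lambda_path = _lambda_path(lam_max, n_lambda, min_ratio)
        lambda_path = np.asarray(lambda_path, float)
        if lambda_path.size == 0:
            raise ValueError("empty lambda path")
        P = A.shape[1]
        coefs = np.zeros((P, lambda_path.size))
        beta = np.zeros(P)
        for i, lam in enumerate(lambda_path):
            enet_coordinate_descent(A, b, float(n0), float(lam), float(alpha),
                                    beta, max_iter, tol)
            coefs[:, i] = beta
        intercepts = np.full(lambda_path.size, self.y.mean())
        return coefs, intercepts, lambda_path

    # -- binomial via penalized IRLS on the augmented system ---------------
    def _fit_binomial(self, rho, alpha, lambda_path, n_lambda, min_ratio,
                      max_iter, tol, irls_iter=25, irls_tol=1e-6):
        Xs = self.views
        y = self.y
        n0 = Xs[0].shape[0]
        Xcat = np.hstack(Xs)
        A_pen, _ = build_augmented_design(Xs, np.zeros(n0), rho)
        A_pen = A_pen[n0:]  # agreement blocks only; observation block reweighted per step
        if lambda_path is None:
            a_eff = max(alpha, _ALPHA_FLOOR)
            p0 = y.mean()
            lam_max = np.abs(Xcat.T @ (y - p0)).max() / (n0 * a_eff) * (1 + 1e-8)
            lambda_path = _lambda_path(lam_max, n_lambda, min_ratio)
        lambda_path = np.asarray(lambda_path, float)
        if lambda_path.size == 0:
            raise ValueError("empty lambda path")
        P = Xcat.shape[1]
        coefs = np.zeros((P, lambda_path.size))
        intercepts = np.zeros(lambda_path.size)
        beta = np.zeros(P)
        b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
        for i, lam in enumerate(lambda_path):
            for _ in range(irls_iter):
                eta = b0 + Xcat @ beta
                mu = _sigmoid(eta)
                w = np.clip(mu * (1 - mu), 1e-5, None)
                z = eta + (y - mu) / w
                sw = np.sqrt(w)
                wm_z = np.average(z, weights=w)
                wm_x = np.average(Xcat, axis=0, weights=w)
                # weighted, centered observation block + unweighted agreement blocks
                A = np.vstack([sw[:, None] * (Xcat - wm_x), A_pen])
                b = np.concatenate([sw * (z - wm_z), np.zeros(A_pen.shape[0])])
                beta_old = beta.copy()
                enet_coordinate_descent(A, b, float(n0), float(lam), float(alpha),
                                        beta, max_iter, tol)
                b0 = float(wm_z - wm_x @ beta)
                if np.abs(beta - beta_old).max() < irls_tol:
                    break
            coefs[:, i] = beta
            intercepts[i] = b0
        return coefs, intercepts, lambda_path

    def fit(self, rho: float = 0.0, alpha: float = 1.0, lambda_path=None,
            n_lambda: int = 50, lambda_min_ratio: float = 1e-3,
            max_iter: int = 1000, tol: float = 1e-7) -> CoopResults:
        """Fit the full λ path (warm starts, decreasing λ)."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        fitter = self._fit_gaussian if self.family == "gaussian" else self._fit_binomial
        coefs, intercepts, path = fitter(rho, alpha, lambda_path, n_lambda,
                                         lambda_min_ratio, max_iter, tol)
        if np.any(np.diff(path) >= 0):
            raise ValueError("lambda path must be strictly decreasing")
        return CoopResults(coefs, intercepts, path, rho, alpha, self.family,
                           self.view_slices, self._names, self._features)

    def objective(self, beta: np.ndarray, lam: float, rho: float,
                  alpha: float) -> float:
        """Gaussian penalized objective at a stacked coefficient vector."""
        A, b = build_augmented_design(self.views, self.y, rho)
        n0 = self.views[0].shape[0]
        resid = b - A @ beta
        return float(resid @ resid / (2 * n0)
                     + lam * (alpha * np.abs(beta).sum()
                              + 0.5 * (1 - alpha) * beta @ beta))


def fit_coop(views, y, rho: float = 0.0, alpha: float = 1.0,
             lambda_path=None, family: str = "gaussian", **kw) -> CoopResults:
    """Functional wrapper around :class:`CooperativeNet`."""
    return CooperativeNet(views, y, family=family).fit(
        rho=rho, alpha=alpha, lambda_path=lambda_path, **kw)


def predict(results: CoopResults, views, lam: float | None = None) -> np.ndarray:
    return results.predict(views, lam)


@dataclass
class LateFusionResults:
    """Per-view elastic-net models whose predictions are averaged."""

    models: list[CoopResults]
    family: str

    def predict(self, views) -> np.ndarray:
        Xs = _as_matrices(views)
        preds = [m.predict([X]) for m, X in zip(self.models, Xs)]
        return np.mean(preds, axis=0)

    def summary(self) -> str:
        return (f"Late fusion ensemble of {len(self.models)} single-view models "
                f"(family={self.family})")


def fit_late_fusion(views, y, alpha: float = 1.0, family: str = "gaussian",
                    cv: int = 5, seed: int = 0, **kw) -> LateFusionResults:
    """Late-fusion endpoint: one CV-tuned elastic net per view, predictions averaged."""
    from .evaluate import _deviance, stratified_folds  # local import, no cycle at module load

    Xs = _as_matrices(views)
    y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    if family == "binomial":
        folds = stratified_folds(y.astype(int), cv, seed)
    else:
        folds = rng.permutation(n) % cv
    models = []
    for X in Xs:
        model = CooperativeNet([X], y, family=family)
        full = model.fit(rho=0.0, alpha=alpha, **kw)
        losses = np.zeros((cv, full.lambda_path.size))
        for f in range(cv):
            tr, te = folds != f, folds == f
            fit = CooperativeNet([X[tr]], y[tr], family=family).fit(
                rho=0.0, alpha=alpha, lambda_path=full.lambda_path, **kw)
            for i in range(full.lambda_path.size):
                pred = fit.predict([X[te]], fit.lambda_path[i])
                if family == "binomial":
                    losses[f, i] = _deviance(y[te], pred)
                else:
                    losses[f, i] = float(np.mean((y[te] - pred) ** 2))
        best = int(np.argmin(losses.mean(axis=0)))
        full.selected_lambda = float(full.lambda_path[best])
        models.append(full)
    return LateFusionResults(models, family)
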