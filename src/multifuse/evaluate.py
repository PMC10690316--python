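"""Repeated stratified nested cross-validation and model comparison.

The protocol: the outer loop (default 5 folds) estimates generalization
performance; inside each outer-training fold an inner loop (default 10
folds) grid-searches the elastic-net mix α and agreement weight ρ by mean
binomial deviance, with λ chosen at the minimum-deviance point of its path.
The whole procedure is repeated (default 30 times) with fresh outer splits
and the repeat-level scores are averaged.  Standardization parameters are
re-estimated inside each outer-training fold, so no information from the
held-out fold leaks into tuning.

Between-model comparison follows the heteroscedasticity-robust route:
Bartlett's test for equality of variances, Welch's ANOVA when variances
differ, and Games-Howell pairwise post-hoc tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .coop import CooperativeNet, CoopResults

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVResult",
    "stratified_folds",
    "nested_cv",
    "auc",
    "accuracy",
    "compare_models",
]


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (values 0..k-1 per sample)."""
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assign[test_idx] = f
    return assign


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (½ credit for ties)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def accuracy(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    return float(np.mean((np.asarray(scores) >= threshold).astype(int)
                         == np.asarray(y, int)))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, −2·mean log-likelihood."""
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class CVConfig:
    """Settings for repeated stratified nested cross-validation."""

    outer_folds: int = 5
    inner_folds: int = 10
    repeats: int = 30
    alpha_grid: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    rho_grid: tuple = (0.0, 0.1, 0.25, 0.5, 1.0)
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    seed: int = 0
    family: str = "binomial"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.alpha_grid or not self.rho_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class CVResult:
    """Per-repeat scores and their summary from :func:`nested_cv`."""

    per_repeat_auc: np.ndarray
    per_repeat_accuracy: np.ndarray
    chosen_hyperparams: tuple[float, float]  # modal (alpha, rho) across outer folds
    hyperparam_counts: dict = field(default_factory=dict)
    config: CVConfig | None = None

    @property
    def mean_auc(self) -> float:
        return float(self.per_repeat_auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.per_repeat_auc.std(ddof=1)) if len(self.per_repeat_auc) > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_repeat_accuracy.mean())

    @property
    def sd_accuracy(self) -> float:
        return (float(self.per_repeat_accuracy.std(ddof=1))
                if len(self.per_repeat_accuracy) > 1 else 0.0)

    def summary(self) -> str:
        a, r = self.chosen_hyperparams
        return (f"Nested CV over {len(self.per_repeat_auc)} repeats\n"
                f"  AUC      {self.mean_auc:.3f} +/- {self.sd_auc:.3f}\n"
                f"  accuracy {self.mean_accuracy:.3f} +/- {self.sd_accuracy:.3f}\n"
                f"  modal hyperparameters: alpha={a} rho={r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeat": np.arange(1, len(self.per_repeat_auc) + 1),
            "auc": self.per_repeat_auc,
            "accuracy": self.per_repeat_accuracy,
        })


def _standardize_blocks(train_blocks, test_blocks):
    """Columnwise standardization fit on train rows only; constants dropped."""
    tr_out, te_out = [], []
    for Xtr, Xte in zip(train_blocks, test_blocks):
        m = Xtr.mean(axis=0)
        s = Xtr.std(axis=0, ddof=1)
        keep = s > 0
        tr_out.append((Xtr[:, keep] - m[keep]) / s[keep])
        te_out.append((Xte[:, keep] - m[keep]) / s[keep])
    return tr_out, te_out


def _tune_inner(train_blocks, y_tr, config: CVConfig, seed: int):
    """Inner-loop grid search; returns (alpha, rho, lambda) at minimum deviance."""
    folds = stratified_folds(y_tr, config.inner_folds, seed)
    best = None
    for alpha, rho in itertools.product(config.alpha_grid, config.rho_grid):
        path_fit = CooperativeNet(train_blocks, y_tr, family=config.family).fit(
            rho=rho, alpha=alpha, n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio)
        path = path_fit.lambda_path
        losses = np.zeros((config.inner_folds, path.size))
        for f in range(config.inner_folds):
            tr, te = folds != f, folds == f
            blocks_tr = [X[tr] for X in train_blocks]
            blocks_te = [X[te] for X in train_blocks]
            fit = CooperativeNet(blocks_tr, y_tr[tr], family=config.family).fit(
                rho=rho, alpha=alpha, lambda_path=path)
            for i, lam in enumerate(path):
                pred = fit.predict(blocks_te, lam)
                losses[f, i] = (_deviance(y_tr[te], pred)
                                if config.family == "binomial"
                                else float(np.mean((y_tr[te] - pred) ** 2)))
        mean_loss = losses.mean(axis=0)
        i_best = int(np.argmin(mean_loss))
        cand = (float(mean_loss[i_best]), alpha, rho, float(path[i_best]))
        if best is None or cand[0] < best[0]:
            best = cand
    _, alpha, rho, lam = best
    return alpha, rho, lam


def nested_cv(views, y, config: CVConfig | None = None,
              inspect_hook=None) -> CVResult:
    """Repeated stratified nested CV of the cooperative model.

    ``inspect_hook(repeat, fold, train_idx, test_idx, n_tuning_rows)`` is an
    optional instrumentation callback; tests use it to assert that tuning
    only ever sees outer-training rows.
    """
    from .coop import _as_matrices

    config = config or CVConfig()
    Xs = _as_matrices(views)
    y = np.asarray(y, int)
    per_auc, per_acc = [], []
    chosen: list[tuple[float, float]] = []
    rng = np.random.default_rng(config.seed)
    for rep in range(config.repeats):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        folds = stratified_folds(y, config.outer_folds, rep_seed)
        fold_auc, fold_acc = [], []
        for f in range(config.outer_folds):
            tr, te = folds != f, folds == f
            blocks_tr, blocks_te = _standardize_blocks(
                [X[tr] for X in Xs], [X[te] for X in Xs])
            alpha, rho, lam = _tune_inner(blocks_tr, y[tr], config,
                                          seed=rep_seed + f + 1)
            if inspect_hook is not None:
                inspect_hook(rep, f, np.where(tr)[0], np.where(te)[0],
                             blocks_tr[0].shape[0])
            fit = CooperativeNet(blocks_tr, y[tr], family=config.family).fit(
                rho=rho, alpha=alpha, n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio)
            pred = fit.predict(blocks_te, lam)
            fold_auc.append(auc(pred, y[te]))
            fold_acc.append(accuracy(pred, y[te]))
            chosen.append((alpha, rho))
        per_auc.append(np.mean(fold_auc))
        per_acc.append(np.mean(fold_acc))
        logger.info("nested CV repeat %d/%d: AUC=%.3f acc=%.3f",
                    rep + 1, config.repeats, per_auc[-1], per_acc[-1])
    counts = pd.Series(chosen).value_counts()
    return CVResult(np.array(per_auc), np.array(per_acc),
                    counts.index[0], counts.to_dict(), config)


@dataclass
class ModelComparison:
    """Bartlett / Welch ANOVA / Games-Howell comparison across score groups."""

    bartlett_stat: float
    bartlett_p: float
    equal_variances: bool
    welch_f: float | None
    welch_df: tuple[float, float] | None
    welch_p: float | None
    pairwise: pd.DataFrame | None

    def summary(self) -> str:
        lines = [f"Bartlett: stat={self.bartlett_stat:.3f} p={self.bartlett_p:.4g} "
                 f"(equal variances: {self.equal_variances})"]
        if self.welch_p is not None:
            lines.append(f"Welch ANOVA: F={self.welch_f:.3f} "
                         f"df=({self.welch_df[0]:.1f}, {self.welch_df[1]:.1f}) "
                         f"p={self.welch_p:.4g}")
        if self.pairwise is not None:
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def compare_models(groups: dict[str, np.ndarray] | list[np.ndarray]
                   ) -> ModelComparison:
    """Compare per-repeat score distributions of two or more models."""
    import pingouin as pg

    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], float) for k in names]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        names = [f"model{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs at least 3 values")
    if any(np.std(a) == 0 for a in arrays):
        raise ValueError("a group has zero variance; Bartlett's test is undefined")
    b_stat, b_p = stats.bartlett(*arrays)
    long = pd.DataFrame({
        "score": np.concatenate(arrays),
        "model": np.repeat(names, [len(a) for a in arrays]),
    })
    welch = pg.welch_anova(data=long, dv="score", between="model")
    gh = pg.pairwise_gameshowell(data=long, dv="score", between="model")
    return ModelComparison(
        bartlett_stat=float(b_stat), bartlett_p=float(b_p),
        equal_variances=bool(b_p >= 0.05),
        welch_f=float(welch["F"].iloc[0]),
        welch_df=(float(welch["ddof1"].iloc[0]), float(welch["ddof2"].iloc[0])),
        welch_p=float(welch["p_unc"].iloc[0]),
        pairwise=gh[["A", "B", "T", "df", "pval"]],
    )
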