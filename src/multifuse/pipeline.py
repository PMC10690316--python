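"""Configuration-driven pipeline orchestration.

``run_pipeline`` executes the analysis graph — simulate → encode →
sparse CCA / multi-CCA → cooperative learning / nested CV → report — from a
validated :class:`RunConfig`, writing every artifact together with a
manifest (config hash, seed, package versions) so identical configurations
reproduce stochastic stages bit-identically.  A single global seed is
fanned out to per-stage seeds through :func:`numpy.random.SeedSequence`, so
each stage's randomness is independent of stage order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coop import CooperativeNet
from .data import align_views, standardize, write_feature_matrix
from .evaluate import CVConfig, nested_cv
from .scca import SparseCCA, MultiCCA, cca_permute, multi_cca_permute
from .simulate import (MultiViewScenario, PhylogenyScenario, gen_multiview,
                       gen_phylogeny)
from .viral import (binary_encode, cosine_dissimilarity, iqr_filter,
                    mds_project, train_skipgram, write_catalog)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "embed", "scca", "multicca", "coop", "nestedcv")

_SCHEMA: dict[str, type] = {
    "stages": list,
    "seed": int,
    "out_dir": str,
    "log_level": str,
    "views": list,
    "outcome": str,
    "simulate": dict,
    "embed": dict,
    "scca": dict,
    "multicca": dict,
    "coop": dict,
    "nestedcv": dict,
}

_LIST_KEYS = {"stages", "views"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``validate_config``)."""

    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    seed: int = 0
    out_dir: str = "multifuse_out"
    log_level: str = "INFO"
    views: list[str] = field(default_factory=list)
    outcome: str | None = None
    # the default end-to-end run simulates three views (so the multi-view
    # stage applies) and uses a scaled-down CV protocol; the full repeated
    # protocol is available through explicit configuration
    simulate: dict = field(default_factory=lambda: {
        "multiview": {"n": 150, "p": [30, 30, 20]}, "phylogeny": {}})
    embed: dict = field(default_factory=dict)
    scca: dict = field(default_factory=dict)
    multicca: dict = field(default_factory=dict)
    coop: dict = field(default_factory=dict)
    nestedcv: dict = field(default_factory=lambda: {
        "repeats": 2, "inner_folds": 5, "alpha_grid": [0.2, 1.0],
        "rho_grid": [0.0, 0.5], "n_lambda": 30})

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and schema-validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    for key, typ in _SCHEMA.items():
        if key not in raw:
            continue
        if key in _LIST_KEYS and not isinstance(raw[key], list):
            logger.info("coercing scalar %r to singleton list", key)
            raw[key] = [raw[key]]
        elif typ is int and isinstance(raw[key], int):
            pass
        elif not isinstance(raw[key], typ) and raw[key] is not None:
            raise ValueError(f"config key {key!r} must be {typ.__name__}")
    cfg = RunConfig(**raw)
    for stage in cfg.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    for v in cfg.views:
        if not Path(v).exists():
            raise ValueError(f"view path does not exist: {v}")
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    dataset = None
    catalog = None
    if "simulate" in config.stages:
        sseed = stage_seed(config.seed, "simulate")
        mv_params = dict(config.simulate.get("multiview", {}))
        mv_params.setdefault("seed", sseed)
        if "p" in mv_params:
            mv_params["p"] = tuple(mv_params["p"])
        dataset, _ = gen_multiview(MultiViewScenario(**mv_params))
        ph_params = dict(config.simulate.get("phylogeny", {}))
        ph_params.setdefault("seed", sseed + 1)
        catalog, _ = gen_phylogeny(PhylogenyScenario(**ph_params))
        for v in dataset.views:
            write_feature_matrix(v, out / f"{v.view_name}.csv")
        write_catalog(catalog, out / "catalog.jsonl")
        (out / "outcome.csv").write_text(
            "sample_id,outcome\n" + "".join(
                f"{s},{y}\n" for s, y in zip(dataset.sample_ids, dataset.outcome)),
            encoding="utf-8")
        summary["simulate"] = {"n": dataset.n_samples,
                               "n_strains": catalog.n_strains}
        logger.info("simulate: n=%d samples, %d strains", dataset.n_samples,
                    catalog.n_strains)

    if dataset is None and config.views:
        from .data import read_feature_matrix, read_outcome
        views = [read_feature_matrix(p) for p in config.views]
        outcome = read_outcome(config.outcome) if config.outcome else None
        dataset = align_views(views, outcome)
        logger.info("aligned %d views to n=%d common samples",
                    len(views), dataset.n_samples)

    embedding = None
    if "embed" in config.stages:
        if catalog is None:
            raise ValueError("embed stage requires a mutation catalog "
                             "(run simulate or provide one)")
        eseed = stage_seed(config.seed, "embed")
        params = config.embed
        filtered, removed = iqr_filter(catalog)
        logger.info("embed: %d strains after IQR filter (removed %d)",
                    filtered.n_strains, len(removed))
        embedding = train_skipgram(
            filtered, d=params.get("dim", 16),
            window=params.get("window", 200),
            epochs=params.get("epochs", 5), seed=eseed,
            min_count=params.get("min_count", 1))
        emb_fm = embedding.to_feature_matrix()
        write_feature_matrix(emb_fm, out / "strain_embedding.csv")
        proj = mds_project(cosine_dissimilarity(embedding.strain_vectors),
                           seed=eseed)
        proj.to_frame(embedding.strain_ids).to_csv(out / "strain_mds.csv",
                                                   index=False)
        _write_json(out / "mds.json", {"stress": proj.stress})
        summary["embed"] = {"n_strains": embedding.strain_vectors.shape[0],
                            "dim": embedding.d,
                            "vocab": len(embedding.vocab),
                            "removed_outliers": len(removed),
                            "mds_stress": proj.stress}

    if dataset is not None:
        dataset_std, _ = standardize(dataset)

    if "scca" in config.stages:
        if dataset is None:
            raise ValueError("scca stage requires views")
        sseed = stage_seed(config.seed, "scca")
        params = config.scca
        x, z = dataset_std.views[0], dataset_std.views[1]
        tuning = cca_permute(x, z, grid=params.get("l1_grid"),
                             n_permutations=params.get("n_perm", 100),
                             seed=sseed)
        res = SparseCCA(x, z).fit(*tuning.best, K=params.get("k", 1))
        res.loadings_frame().to_csv(out / "scca_loadings.csv", index=False)
        tuning.to_frame().to_csv(out / "scca_tuning.csv", index=False)
        summary["scca"] = {
            "best_l1": list(tuning.best),
            "zstat": float(tuning.zstats[tuning.best_index]),
            "pvalue": tuning.pvalue,
            "correlation": float(res.correlations[0]),
            "nonzero": list(res.nonzero_counts[0]),
        }
        logger.info("scca: best=%s corr=%.3f p=%.3g", tuning.best,
                    res.correlations[0], tuning.pvalue)

    if "multicca" in config.stages:
        if dataset is None or len(dataset.views) < 3:
            raise ValueError("multicca stage requires at least 3 views")
        mseed = stage_seed(config.seed, "multicca")
        params = config.multicca
        tuning = multi_cca_permute(dataset_std, grid=params.get("grid"),
                                   n_permutations=params.get("n_perm", 100),
                                   seed=mseed)
        res = MultiCCA(dataset_std).fit(tuning.best, K=params.get("k", 1))
        res.pairwise_frame().to_csv(out / "multicca_correlations.csv")
        summary["multicca"] = {
            "penalties": [float(c) for c in res.penalties],
            "zstat": float(tuning.zstats[tuning.best_index]),
            "pvalue": tuning.pvalue,
            "objective": res.objective,
        }

    if "coop" in config.stages:
        if dataset is None or dataset.outcome is None:
            raise ValueError("coop stage requires views and an outcome")
        params = config.coop
        model = CooperativeNet(dataset_std, family=params.get("family", "binomial"))
        fit = model.fit(rho=params.get("rho", 0.1),
                        alpha=params.get("alpha", 0.2),
                        n_lambda=params.get("n_lambda", 50))
        lam = params.get("lambda", float(fit.lambda_path[-1]))
        fit.selected_lambda = lam
        fit.coefficients_frame(lam).to_csv(out / "coop_coefficients.csv",
                                           index=False)
        summary["coop"] = {"rho": fit.rho, "alpha": fit.alpha,
                           "lambda": lam,
                           "nonzero": fit.nonzero_counts(lam)}

    if "nestedcv" in config.stages:
        if dataset is None or dataset.outcome is None:
            raise ValueError("nestedcv stage requires views and an outcome")
        nseed = stage_seed(config.seed, "nestedcv")
        params = dict(config.nestedcv)
        params.setdefault("seed", nseed)
        for k in ("alpha_grid", "rho_grid"):
            if k in params:
                params[k] = tuple(params[k])
        cv = CVConfig(**params)
        res = nested_cv(dataset.matrices(), dataset.outcome, cv)
        res.to_frame().to_csv(out / "nestedcv_per_repeat.csv", index=False)
        summary["nestedcv"] = {
            "mean_auc": res.mean_auc, "sd_auc": res.sd_auc,
            "mean_accuracy": res.mean_accuracy, "sd_accuracy": res.sd_accuracy,
            "chosen": list(res.chosen_hyperparams),
        }
        logger.info("nested CV: AUC %.3f +/- %.3f", res.mean_auc, res.sd_auc)

    _write_json(out / "summary.json", summary)
    _write_json(out / "manifest.json", {
        "config_hash": config.digest(),
        "seed": config.seed,
        "multifuse_version": __version__,
        "numpy_version": np.__version__,
    })
    return out
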