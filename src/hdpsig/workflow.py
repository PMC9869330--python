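"""End-to-end pipelines: simulate -> (downsample) -> discover -> assess.

``run_discovery`` chains the stages with scheme-dependent defaults: SBS96
catalogs get the beta = 20 concentration prior and a 3000-mutation
downsampling threshold; ID83 catalogs get beta = 50 and no downsampling.
``run_benchmark`` repeats simulate/discover/assess over a list of seeds and
tabulates PPV, TPR, mean cosine similarity and the composite measure with
mean/SD summary rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .assess import MatchConfig, match_signatures, signature_metrics
from .catalogs import MutationCatalog, write_signatures
from .downsample import DEFAULT_SBS_THRESHOLD, downsample_spectra
from .extraction import (
    ExtractionResult,
    extract_signatures,
    pool_clusters,
    signature_diagnostics,
)
from .hierarchy import build_hierarchy
from .sampler import ConcentrationPrior, SamplerConfig, run_multi_chain
from .simulate import GroundTruth, NoiseModel, PrevalenceModel, synthesize_dataset

__all__ = ["RunConfig", "PipelineError", "desk_profile", "paper_profile",
           "run_discovery", "run_benchmark"]

_AUTO = "auto"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a discovery run from a catalog + seed."""

    scheme: str = "SBS96"
    use_groups: bool = False          # three-layer hierarchy over cancer types
    burnin: int = 5000
    n_chains: int = 20
    n_samples: int = 200              # Gibbs samples per chain
    spacing: int = 100                # sweeps between recorded samples
    prior_shape: float = 1.0
    prior_beta: float | str = _AUTO   # auto: 20 for SBS96, 50 for ID83
    init_dishes: int = 10
    downsample_threshold: int | None | str = _AUTO  # auto: 3000 SBS96, off ID83
    cohesion_threshold: float = 0.90
    support_cutoff: float = 0.9
    seed: int = 0
    n_jobs: int = 1
    outdir: str | None = None
    checkpoint_path: str | None = None

    def resolved(self) -> "RunConfig":
        """Apply scheme-dependent defaults and validate."""
        beta = self.prior_beta
        if beta == _AUTO:
            beta = 50.0 if self.scheme == "ID83" else 20.0
        thr = self.downsample_threshold
        if thr == _AUTO:
            thr = None if self.scheme == "ID83" else DEFAULT_SBS_THRESHOLD
        cfg = replace(self, prior_beta=float(beta), downsample_threshold=thr)
        if cfg.prior_beta <= 0 or cfg.prior_shape <= 0:
            raise ValueError("gamma prior shape and beta must be positive")
        if cfg.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < cfg.support_cutoff <= 1:
            raise ValueError("support_cutoff must be in (0, 1]")
        if not 0 < cfg.cohesion_threshold <= 1:
            raise ValueError("cohesion_threshold must be in (0, 1]")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def desk_profile(**overrides) -> RunConfig:
    """Small sampling profile for interactive use and continuous testing."""
    base = dict(burnin=500, n_chains=4, n_samples=20, spacing=10,
                init_dishes=8)
    base.update(overrides)
    return RunConfig(**base)


def paper_profile(**overrides) -> RunConfig:
    """The typical full-scale profile: 20 chains x 200 samples x spacing 100."""
    base = dict(burnin=5000, n_chains=20, n_samples=200, spacing=100)
    base.update(overrides)
    return RunConfig(**base)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (PipelineError, ValueError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_discovery(catalog: MutationCatalog, config: RunConfig) -> ExtractionResult:
    """Full signature discovery: downsample, sample, group, extract, write.

    Fully reproducible from (catalog, config, seed).  When ``config.outdir``
    is set, signatures, exposures, group supports, diagnostics and a run
    manifest (version, seeds, config hash) are written there.
    """
    config = config.resolved()
    if catalog.scheme.name != config.scheme:
        raise ValueError(
            f"catalog scheme {catalog.scheme.name} != config scheme {config.scheme}"
        )
    work = catalog
    if config.downsample_threshold is not None:
        work = _stage("downsample", downsample_spectra, catalog,
                      config.downsample_threshold)
    groups = catalog.sample_groups if config.use_groups else None
    hier = _stage("hierarchy", build_hierarchy, work.sample_ids, groups)
    sampler_cfg = SamplerConfig(
        burnin=config.burnin,
        n_samples=config.n_samples,
        spacing=config.spacing,
        prior=ConcentrationPrior(config.prior_shape, config.prior_beta),
        seed=config.seed,
        init_dishes=config.init_dishes,
        checkpoint_path=config.checkpoint_path,
    )
    archive = _stage("sampling", run_multi_chain, work, hier, sampler_cfg,
                     n_chains=config.n_chains, n_jobs=config.n_jobs)
    pool = _stage("pooling", pool_clusters, archive)
    result = _stage(
        "extraction", extract_signatures, pool, archive,
        support_cutoff=config.support_cutoff,
        cohesion_threshold=config.cohesion_threshold,
        scheme=catalog.scheme, sample_ids=list(catalog.sample_ids),
    )
    if config.outdir is not None:
        _stage("output", _write_outputs, result, pool, work, catalog, config)
    return result


def _write_outputs(result, pool, work_catalog, catalog, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.K > 0:
        write_signatures(result.signatures, outdir / "signatures.tsv")
        pd.DataFrame(
            result.exposures,
            index=result.signatures.signature_ids,
            columns=catalog.sample_ids,
        ).to_csv(outdir / "exposures.tsv", sep="\t",
                 index_label="Signature", float_format="%.6g")
    rows = [
        (f"hdp.{i + 1}" if retained else f"discarded.{i + 1}",
         retained, g.support, int(g.class_counts.sum()),
         len(g.member_indices), g.single_class)
        for retained, glist in ((True, result.retained_groups),
                                (False, result.discarded_groups))
        for i, g in enumerate(glist)
    ]
    pd.DataFrame(rows, columns=[
        "group", "retained", "support", "total_mutations",
        "n_clusters", "single_class",
    ]).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    diag = signature_diagnostics(result, work_catalog, pool)
    ddir = outdir / "diagnostics"
    ddir.mkdir(exist_ok=True)
    for key, df in diag.items():
        df.to_csv(ddir / (key.replace("/", "_") + ".tsv"), sep="\t", index=False)
    manifest = {
        "hdpsig_version": __version__,
        "seed": config.seed,
        "chain_seeds": [config.seed + i for i in range(config.n_chains)],
        "config": {k: (v if not isinstance(v, float) or np.isfinite(v) else str(v))
                   for k, v in asdict(config).items()},
        "config_hash": config.config_hash(),
        "n_retained": result.K,
        "warning": result.warning,
    }
    with open(outdir / "run_info.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def run_benchmark(
    model: PrevalenceModel,
    truth_signatures,
    noise: NoiseModel,
    seeds: list[int],
    run_config: RunConfig,
    match_config: MatchConfig = MatchConfig(),
) -> pd.DataFrame:
    """Simulate, discover and assess once per seed; summarize with mean/SD.

    Truth for each seed is the set of signatures actually planted in that
    seed's synthetic catalog (non-zero total exposure).
    """
    if not seeds:
        raise ValueError("seeds list must be non-empty")
    rows = []
    for seed in seeds:
        catalog, truth = _stage(
            "simulate", synthesize_dataset, model, truth_signatures, noise, seed
        )
        cfg = replace(run_config, seed=seed,
                      outdir=(f"{run_config.outdir}/seed{seed}"
                              if run_config.outdir else None))
        result = run_discovery(catalog, cfg)
        active = truth.active_signatures()
        match = _stage("assess", match_signatures, result.signatures,
                       active, match_config)
        m = signature_metrics(match)
        rows.append({
            "seed": seed, "K": result.K, "n_truth": active.K,
            "TP": match.TP, "FP": match.FP, "FN": match.FN,
            "PPV": m.PPV, "TPR": m.TPR, "mean_cosine": m.mean_cosine,
            "composite": m.composite,
        })
    df = pd.DataFrame(rows)
    metric_cols = ["PPV", "TPR", "mean_cosine", "composite"]
    summary = pd.DataFrame({
        "seed": ["mean", "SD"],
        **{c: [df[c].mean(), df[c].std(ddof=1) if len(df) > 1 else 0.0]
           for c in metric_cols},
    })
    return pd.concat([df, summary], ignore_index=True)
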