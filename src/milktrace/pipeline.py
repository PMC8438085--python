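"""Configuration-driven end-to-end orchestration.

Sequences rarefaction, normalization, domain merging, co-occurrence
summaries, per-farm edge estimation, FDR control, consensus building and
driver modelling, writing all outputs plus a reproducibility manifest. A
single global seed is fanned out to per-stage sub-seeds through a
counter-based scheme so individual stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cooccurrence as co
from . import driver_models as dm
from . import io_tables as io
from . import synthetic as syn
from . import transfer_network as tn

log = logging.getLogger(__name__)

STAGES = (
    "acquire",
    "rarefy",
    "relative_abundance",
    "merge_domains",
    "cooccurrence",
    "farm_edges",
    "fdr",
    "consensus",
    "driver_models",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (counter-based fan-out, < 2**31)."""
    counter = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    seed: int
    out_dir: str = "milktrace_run"
    # either a simulation scenario ...
    simulate: dict[str, Any] | None = field(default_factory=dict)
    # ... or input files
    counts_prokaryote: str | None = None
    counts_fungal: str | None = None
    metadata: str | None = None
    covariates: str | None = None
    # stage parameters
    depth: int = 10_000
    alpha_edge: float = 0.001
    alpha_consensus: float = 0.001
    n_boot: int = 2000
    use_wto: bool = False
    use_raw_p: bool = False
    renormalize_merged: bool = False
    abundance_transform: str | None = None  # None | "log10"
    shadow_iters: int = 100
    rf_trees: int = 500
    variance_method: str = "sequential"
    aic_direction: str = "both"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("alpha_edge", "alpha_consensus"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.depth <= 0 or self.n_boot <= 0:
            raise ValueError("depth and n_boot must be positive")
        if self.simulate is None:
            for name in ("counts_prokaryote", "counts_fungal", "metadata"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"file mode requires {name}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: {path}")
            if self.covariates is not None and not Path(self.covariates).exists():
                raise FileNotFoundError(f"covariates: {self.covariates}")
        if self.abundance_transform not in (None, "log10"):
            raise ValueError(f"unknown abundance transform {self.abundance_transform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    edges: list[tn.FarmEdgeEstimate]
    consensus: list[tn.ConsensusEdge]
    significant: list[tn.ConsensusEdge]
    reports: list[dict]
    partition: dict[str, co.PartitionCounts]  # per domain, network level
    richness: dict[str, pd.DataFrame]
    manifest: dict
    bundle: syn.SyntheticBundle | None = None


def _scenario_config(cfg: RunConfig) -> syn.ScenarioConfig:
    opts = dict(cfg.simulate or {})
    opts.setdefault("seed", stage_seed(cfg.seed, "acquire"))
    n_genera = {}
    if "n_prok" in opts:
        n_genera["prokaryote"] = opts.pop("n_prok")
    if "n_fungal" in opts:
        n_genera["fungal"] = opts.pop("n_fungal")
    if n_genera:
        full = {"prokaryote": 1917, "fungal": 1080}
        full.update(n_genera)
        opts["n_genera"] = full
    return syn.ScenarioConfig(**opts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write outputs; idempotent for a fixed seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[dict] = []

    def done(stage: str, **info: Any) -> None:
        log.info("stage %s: %s", stage, info)
        stages_done.append({"stage": stage, **info})

    # -- acquire ------------------------------------------------------------
    bundle: syn.SyntheticBundle | None = None
    covariates: pd.DataFrame | None = None
    try:
        if config.simulate is not None:
            bundle = syn.generate_dataset(_scenario_config(config))
            tables = bundle.tables
            metadata = bundle.metadata
            covariates = bundle.covariates
            bundle.write(out / "data")
        else:
            tables = {
                "prokaryote": io.read_genus_table(
                    config.counts_prokaryote, "prokaryote"
                ),
                "fungal": io.read_genus_table(config.counts_fungal, "fungal"),
            }
            metadata = io.read_metadata(config.metadata)
            if config.covariates:
                covariates = pd.read_csv(
                    config.covariates, sep="\t", index_col="farm"
                )
        done("acquire", samples=sum(t.n_samples for t in tables.values()),
             farms=len(metadata.farms))
    except Exception as err:
        raise RuntimeError(f"stage 'acquire' failed: {err}") from err

    # -- rarefy / normalize / merge ------------------------------------------
    try:
        rarefied = {
            dom: io.rarefy(t, depth=config.depth, seed=stage_seed(config.seed, "rarefy"))
            for dom, t in tables.items()
        }
        done("rarefy", depth=config.depth)
        relab = {dom: io.to_relative_abundance(t) for dom, t in rarefied.items()}
        done("relative_abundance")
        merged = io.merge_domains(
            relab["prokaryote"], relab["fungal"],
            renormalize=config.renormalize_merged,
        )
        done("merge_domains", genera=merged.values.shape[1])
    except Exception as err:
        raise RuntimeError(f"stage 'normalize' failed: {err}") from err

    # -- co-occurrence summaries ---------------------------------------------
    partition: dict[str, co.PartitionCounts] = {}
    richness: dict[str, pd.DataFrame] = {}
    for dom, table in rarefied.items():
        per_farm = co.compartment_genus_sets(table, metadata, by_farm=True)
        partition[dom] = co.venn_partition(co.merge_farm_sets(per_farm))
        richness[dom] = co.richness_summary(per_farm)
        partition[dom].to_frame().to_csv(
            out / f"venn_partition_{dom}.tsv", sep="\t", index=False
        )
        richness[dom].to_csv(out / f"richness_{dom}.tsv", sep="\t",
                             float_format=io._TSV_FLOAT)
        co.region_frequency(per_farm).to_csv(
            out / f"region_frequency_{dom}.tsv", sep="\t", index=False,
            float_format=io._TSV_FLOAT,
        )
    done("cooccurrence", **{f"union_{d}": partition[d].total for d in partition})

    # -- per-farm edges, FDR, consensus ---------------------------------------
    estimates = tn.farm_pair_estimates(
        merged, metadata, transform=config.abundance_transform
    )
    done("farm_edges", tested=len(estimates))
    tn.fdr_adjust(estimates, alpha=config.alpha_edge, use_raw_p=config.use_raw_p)
    done("fdr", significant=sum(e.significant for e in estimates))

    nets = []
    for farm in sorted({e.farm for e in estimates}):
        net = tn.build_farm_network([e for e in estimates if e.farm == farm])
        nets.append(tn.wto_transform(net) if config.use_wto else net)
    consensus_edges = tn.consensus(
        nets, n_boot=config.n_boot, seed=stage_seed(config.seed, "consensus"),
        alpha=config.alpha_consensus,
    )
    significant = tn.significant_links(consensus_edges, alpha=config.alpha_consensus)
    done("consensus", edges=len(consensus_edges), significant=len(significant))

    # -- driver models ---------------------------------------------------------
    reports: list[dict] = []
    if covariates is not None:
        farm_r = _per_farm_link_strengths(estimates)
        for edge in significant:
            key = f"{edge.pair[0]}-{edge.pair[1]}"
            try:
                reports.append(
                    dm.link_driver_analysis(
                        farm_r[edge.pair],
                        covariates,
                        link_name=key,
                        shadow_iters=config.shadow_iters,
                        rf_trees=config.rf_trees,
                        variance_method=config.variance_method,
                        aic_direction=config.aic_direction,
                        seed=stage_seed(config.seed, "driver_models"),
                    )
                )
            except ValueError as err:
                log.warning("driver model for %s skipped: %s", key, err)
    done("driver_models", models=len(reports))

    # -- outputs + manifest -----------------------------------------------------
    io.write_outputs(
        tn.edges_frame(estimates), tn.consensus_frame(consensus_edges), reports, out
    )
    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": stages_done,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        config=config,
        edges=estimates,
        consensus=consensus_edges,
        significant=significant,
        reports=reports,
        partition=partition,
        richness=richness,
        manifest=manifest,
        bundle=bundle,
    )


def _per_farm_link_strengths(
    estimates: list[tn.FarmEdgeEstimate],
) -> dict[tuple[str, str], pd.Series]:
    """Per-farm raw correlation per compartment pair (NaN where undefined)."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    for e in estimates:
        out.setdefault(e.pair, {})[e.farm] = np.nan if e.r is None else e.r
    return {pair: pd.Series(d).sort_index() for pair, d in out.items()}


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    import milktrace

    return {
        "milktrace": milktrace.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }
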