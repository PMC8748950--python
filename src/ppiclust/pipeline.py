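"""Configurable end-to-end pipeline runs and cross-cohort comparison.

A :class:`RunConfig` names the inputs (interactome plus either a raw variant
table with a sample sheet, or precomputed per-sample seed lists) and all
analysis parameters; :func:`run_pipeline` executes
variants -> sample networks -> clustering (-> separation when at least two
clusters are reported) and writes every artifact plus a machine-readable
summary into the output directory.  Outputs are deterministic: the same
config and inputs give byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import separation as sep
from .interactome import Interactome, read_interactome, read_symbol_map
from .model import NetworkClusterModel, NetworkClusterResults
from .variants import (FilterThresholds, SampleSeedSet, read_sample_sheet,
                       read_variant_table)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (serialised into the output dir)."""

    interactome: str
    out_dir: str
    # input mode: exactly one of (variants + sample_sheet) or seeds
    variants: Optional[str] = None
    sample_sheet: Optional[str] = None
    seeds: Optional[str] = None
    symbol_map: Optional[str] = None
    # parameters
    min_confidence: int = 700
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    association_method: str = "trend_pca_adjusted"
    n_pcs: int = 10
    K: int = 30
    max_path_length: int = 2
    alpha: float = 0.001
    min_size: int = 3
    rng_seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.seeds is None) == (self.variants is None):
            raise ValueError(
                "config must set exactly one input mode: 'seeds' or "
                "'variants' (with 'sample_sheet')"
            )
        if self.variants is not None and self.sample_sheet is None:
            raise ValueError("variant-table input requires a sample_sheet")
        for name in ("interactome", "variants", "sample_sheet", "seeds", "symbol_map"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path '{name}' does not exist: {path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_seed_lists(path) -> list[SampleSeedSet]:
    """Read a seeds TSV (sample_id, group, rank, gene[, p]) back into seed sets."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    required = {"sample_id", "group", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"seed list must have columns {sorted(required)}")
    if "rank" in df.columns:
        df = df.sort_values(["sample_id", "rank"], kind="stable")
    out = []
    for (sid, group), sub in df.groupby(["sample_id", "group"], sort=True):
        pvals = tuple(float(p) for p in sub["p"]) if "p" in sub.columns and sub["p"].notna().all() else ()
        out.append(SampleSeedSet(str(sid), str(group),
                                 tuple(g.upper() for g in sub["gene"]), pvals))
    return out


def run_pipeline(cfg: RunConfig) -> NetworkClusterResults:
    """Execute the full pipeline described by ``cfg`` and write the run directory."""
    cfg.validate()
    logging.getLogger("ppiclust").setLevel(cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    try:
        symbol_map = read_symbol_map(cfg.symbol_map) if cfg.symbol_map else None
        interactome = read_interactome(cfg.interactome, cfg.min_confidence, symbol_map)
    except Exception as exc:
        raise StageError("interactome", str(exc)) from exc

    try:
        if cfg.seeds is not None:
            seed_sets = read_seed_lists(cfg.seeds)
            model = NetworkClusterModel(
                seed_sets, interactome,
                max_path_length=cfg.max_path_length,
                alpha=cfg.alpha, min_size=cfg.min_size,
            )
        else:
            variants = read_variant_table(cfg.variants)
            sheet = read_sample_sheet(cfg.sample_sheet)
            model = NetworkClusterModel.from_variant_table(
                variants, sheet, interactome,
                thresholds=cfg.thresholds, K=cfg.K,
                association_method=cfg.association_method, n_pcs=cfg.n_pcs,
                max_path_length=cfg.max_path_length,
                alpha=cfg.alpha, min_size=cfg.min_size,
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("variants", str(exc)) from exc

    try:
        results = model.fit()
    except Exception as exc:
        raise StageError("clustering", str(exc)) from exc

    try:
        results.save(out)
    except Exception as exc:
        raise StageError("output", str(exc)) from exc
    logger.info("pipeline complete: %d samples clustered, %d cluster(s) reported",
                results.n_samples, len(results.clusters))
    return results


def read_unique_genes(run_dir) -> dict[str, set[str]]:
    """Read a run directory's unique-gene lists as {cluster label: gene set}."""
    path = Path(run_dir) / "unique_genes.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact: {path} (was the run completed with >= 1 cluster?)"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.cluster, set()).add(row.gene)
    return out


def compare_cohorts(run_a, run_b, interactome: Interactome) -> pd.DataFrame:
    """Cross-cohort separation matrix between two runs' cluster-unique gene sets.

    Rows are the clusters of ``run_a``, columns those of ``run_b``; a
    ``min_per_row`` column marks each row's most-negative (most similar)
    counterpart.
    """
    sets_a = read_unique_genes(run_a)
    sets_b = read_unique_genes(run_b)
    mat = sep.separation_matrix(sets_a, sets_b, interactome)
    return mat.assign(min_per_row=sep.flag_row_minima(mat))
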