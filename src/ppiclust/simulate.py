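"""Synthetic interactomes and cohorts with known ground truth.

Everything the pipeline consumes can be generated here: a modular
(stochastic-block-model) interactome over namespaced synthetic gene symbols
(``G00001`` ...), a case/control cohort with per-sample seed genes, and an
annotated variant table that exercises the full variant stage.  One or more
*planted* case subgroups draw most of their seed genes from a designated
interactome module, mirroring the situation the clustering stage is meant to
detect: a subgroup of patients whose damaging variants concentrate in one
region of the interactome.

Default sizes (500-node / 10-module interactome, 40 cases + 40 controls,
30 seeds per sample, one planted subgroup of 20 cases drawing 25 of its 30
seeds from one module) are chosen so a full pipeline run takes seconds while
the planted subgroup remains clearly recoverable.  All generators are
reproducible given ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome
from .variants import SampleSeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedGroup:
    """A planted case subgroup: ``size`` cases drawing a fraction ``f`` of their
    seeds from interactome module ``module``."""

    size: int
    module: int
    f: float


@dataclass
class SimConfig:
    """Configuration of the synthetic interactome + cohort generators."""

    rng_seed: int = 0
    # interactome
    n_nodes: int = 500
    n_modules: int = 10
    p_within: float = 0.3
    p_between: float = 0.01
    edge_confidence: int = 900
    # cohort
    n_cases: int = 40
    n_controls: int = 40
    K_seeds: int = 30
    planted: tuple[PlantedGroup, ...] = (PlantedGroup(size=20, module=0, f=25 / 30),)
    # variant layer
    variants_per_gene: int = 2
    damaging_frac: float = 0.5
    baseline_maf_range: tuple[float, float] = (0.01, 0.10)
    signal_carrier_p: float = 0.9
    # optional two-subpopulation stratification (Balding–Nichols allele freqs)
    stratified: bool = False
    strat_fst: float = 0.1
    strat_case_frac_pop1: float = 0.8
    strat_control_frac_pop1: float = 0.2

    def validate(self) -> None:
        if not (0 <= self.p_within <= 1 and 0 <= self.p_between <= 1):
            raise ValueError("edge probabilities must be in [0, 1]")
        module_size = self.n_nodes // self.n_modules
        for pg in self.planted:
            if pg.size > self.n_cases:
                raise ValueError("planted subgroup larger than the case group")
            if not 0 <= pg.f <= 1:
                raise ValueError("signal fraction f must be in [0, 1]")
            if not 0 <= pg.module < self.n_modules:
                raise ValueError("planted module id out of range")
            if module_size < int(round(pg.f * self.K_seeds)):
                raise ValueError(
                    f"module of {module_size} genes cannot supply "
                    f"{round(pg.f * self.K_seeds)} seeds"
                )
        if self.p_within * (self.n_nodes / self.n_modules - 1) < 1e-9 and self.p_between * self.n_nodes < 1e-9:
            logger.warning("expected node degree is ~0; networks will be empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [asdict(pg) for pg in self.planted]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["planted"] = tuple(PlantedGroup(**pg) for pg in d.get("planted", ()))
        for key in ("baseline_maf_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Which samples were planted into which module, plus the module gene lists."""

    sample_groups: dict[str, str]  # sample -> case/control
    planted: dict[str, Optional[int]]  # sample -> module id (None = background)
    modules: dict[int, tuple[str, ...]]

    def planted_samples(self, module: Optional[int] = None) -> list[str]:
        return sorted(
            s for s, m in self.planted.items()
            if m is not None and (module is None or m == module)
        )

    def to_json(self, path) -> None:
        payload = {
            "sample_groups": self.sample_groups,
            "planted": self.planted,
            "modules": {str(k): list(v) for k, v in self.modules.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            sample_groups=payload["sample_groups"],
            planted={k: (None if v is None else int(v)) for k, v in payload["planted"].items()},
            modules={int(k): tuple(v) for k, v in payload["modules"].items()},
        )


# ---------------------------------------------------------------------------
# Generators

def _gene_name(i: int) -> str:
    return f"G{i + 1:05d}"  # namespaced so fixtures can never look like real genes


def simulate_interactome(cfg: SimConfig) -> tuple[Interactome, dict[int, tuple[str, ...]]]:
    """Stochastic-block-model interactome with ``n_modules`` planted modules.

    Returns the interactome and the module -> gene-tuple map.  Reproducible
    for a fixed ``cfg.rng_seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    base = cfg.n_nodes // cfg.n_modules
    sizes = [base + (1 if i < cfg.n_nodes % cfg.n_modules else 0) for i in range(cfg.n_modules)]
    probs = [
        [cfg.p_within if i == j else cfg.p_between for j in range(cfg.n_modules)]
        for i in range(cfg.n_modules)
    ]
    sbm_seed = int(rng.integers(2**31 - 1))
    g = nx.stochastic_block_model(sizes, probs, seed=sbm_seed)
    relabel = {i: _gene_name(i) for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(((a, b, {"confidence": cfg.edge_confidence}) for a, b in g.edges))

    modules: dict[int, tuple[str, ...]] = {}
    start = 0
    for m, size in enumerate(sizes):
        modules[m] = tuple(_gene_name(i) for i in range(start, start + size))
        start += size
    return Interactome(out), modules


def _sample_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    cases = [f"CASE{i + 1:03d}" for i in range(cfg.n_cases)]
    controls = [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)]
    return cases, controls


def make_cohort(cfg: SimConfig, rng: np.random.Generator,
                modules: dict[int, tuple[str, ...]]) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample sheet plus planted-subgroup assignment (planted samples are cases)."""
    cases, controls = _sample_ids(cfg)
    sheet = pd.DataFrame({
        "sample_id": cases + controls,
        "group": ["case"] * len(cases) + ["control"] * len(controls),
    })
    planted: dict[str, Optional[int]] = {s: None for s in cases + controls}
    available = list(cases)
    for pg in cfg.planted:
        chosen = rng.choice(len(available), size=pg.size, replace=False)
        chosen_ids = [available[i] for i in sorted(chosen)]
        for s in chosen_ids:
            planted[s] = pg.module
        available = [s for s in available if planted[s] is None]
    truth = GroundTruth(
        sample_groups=dict(zip(sheet["sample_id"], sheet["group"])),
        planted=planted,
        modules=modules,
    )
    return sheet, truth


def simulate_cohort_seeds(
    interactome: Interactome,
    modules: dict[int, tuple[str, ...]],
    cfg: SimConfig,
) -> tuple[list[SampleSeedSet], GroundTruth]:
    """Draw each sample's seed genes directly (no variant layer).

    Planted samples take ``round(f * K)`` seeds uniformly (without
    replacement) from their module and the remainder uniformly from the whole
    interactome; background samples take all ``K`` seeds uniformly.  No sample
    has duplicate seeds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    sheet, truth = make_cohort(cfg, rng, modules)
    all_genes = np.array(sorted(interactome.nodes))
    seed_sets: list[SampleSeedSet] = []
    for row in sheet.itertuples():
        module = truth.planted[row.sample_id]
        chosen: list[str] = []
        if module is not None:
            pg = next(p for p in cfg.planted if p.module == module)
            k_mod = int(round(pg.f * cfg.K_seeds))
            mod_genes = np.array(modules[module])
            chosen.extend(rng.choice(mod_genes, size=k_mod, replace=False).tolist())
        remaining = cfg.K_seeds - len(chosen)
        pool = np.array([g for g in all_genes if g not in set(chosen)])
        chosen.extend(rng.choice(pool, size=remaining, replace=False).tolist())
        seed_sets.append(SampleSeedSet(row.sample_id, row.group, tuple(chosen)))
    return seed_sets, truth


def balding_nichols_freqs(
    n_variants: int, fst: float, rng: np.random.Generator,
    ancestral_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Two subpopulation allele-frequency vectors with divergence ``fst``."""
    p = rng.uniform(*ancestral_range, size=n_variants)
    if fst <= 0:
        return p, p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b), rng.beta(a, b)


def simulate_stratified_genotypes(
    n_cases: int,
    n_controls: int,
    n_variants: int,
    rng: np.random.Generator,
    fst: float = 0.1,
    case_frac_pop1: float = 0.8,
    control_frac_pop1: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null genotypes confounded by population structure.

    Cases and controls are drawn from two subpopulations at different rates,
    and allele frequencies differ between subpopulations (Balding–Nichols
    with the given Fst), so the *unadjusted* trend test is inflated although
    no variant is truly associated.  Returns ``(G samples x variants doses,
    phenotype 0/1, subpopulation 0/1)``.
    """
    n = n_cases + n_controls
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    pop = np.concatenate([
        (rng.uniform(size=n_cases) < case_frac_pop1).astype(int),
        (rng.uniform(size=n_controls) < control_frac_pop1).astype(int),
    ])
    f1, f2 = balding_nichols_freqs(n_variants, fst, rng)
    freqs = np.where(pop[:, None] == 1, f1[None, :], f2[None, :])
    G = rng.binomial(2, freqs).astype(float)
    return G, y, pop


def simulate_variant_table(
    interactome: Interactome,
    truth: GroundTruth,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotated variant table + sample sheet exercising the full variant stage.

    Per gene, ``cfg.variants_per_gene`` variants are generated; a fraction
    ``damaging_frac`` carry filter-passing annotations (PolyPhen >= 0.957,
    SIFT < 0.05, CADD > 10, ExAC MAF < 0.05), the rest are benign.  Genotypes
    follow per-site cohort allele frequencies drawn from
    ``baseline_maf_range``; planted samples additionally carry at least one
    alternate allele at each damaging variant of their module's genes with
    probability ``signal_carrier_p``.  With ``cfg.stratified`` the cohort is
    split into two subpopulations with Balding–Nichols-divergent frequencies
    (confounded with case status) to exercise the PCA adjustment.

    Positions are spaced 1 kb apart so the 10 bp density QC rule never fires
    on clean synthetic data.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    genes = sorted(interactome.nodes)
    sample_ids = list(truth.sample_groups)
    groups = np.array([truth.sample_groups[s] for s in sample_ids])
    n_samples = len(sample_ids)

    module_of_gene: dict[str, int] = {}
    for m, gl in truth.modules.items():
        for g in gl:
            module_of_gene[g] = m

    if cfg.stratified:
        pop = np.where(
            groups == "case",
            (rng.uniform(size=n_samples) < cfg.strat_case_frac_pop1),
            (rng.uniform(size=n_samples) < cfg.strat_control_frac_pop1),
        ).astype(int)
    else:
        pop = np.zeros(n_samples, dtype=int)

    rows = []
    geno_cols = {s: [] for s in sample_ids}
    pos_counter = 0
    for gi, gene in enumerate(genes):
        for vi in range(cfg.variants_per_gene):
            pos_counter += 1
            damaging = rng.uniform() < cfg.damaging_frac
            if damaging:
                annot = dict(
                    Polyphen2_HDIV_score=float(rng.uniform(0.96, 1.0)),
                    SIFT_score=float(rng.uniform(0.0, 0.04)),
                    CADD_phred=float(rng.uniform(15, 35)),
                    ExAC_ALL=float(rng.uniform(0.001, 0.04)),
                )
            else:
                annot = dict(
                    Polyphen2_HDIV_score=float(rng.uniform(0.0, 0.5)),
                    SIFT_score=float(rng.uniform(0.1, 1.0)),
                    CADD_phred=float(rng.uniform(0, 8)),
                    ExAC_ALL=float(rng.uniform(0.001, 0.3)),
                )
            lo, hi = cfg.baseline_maf_range
            if cfg.stratified:
                f1, f2 = balding_nichols_freqs(1, cfg.strat_fst, rng,
                                               ancestral_range=(max(lo, 1e-4), max(hi, 1e-3)))
                site_freq = np.where(pop == 1, f1[0], f2[0])
            else:
                q = rng.uniform(lo, hi) if hi > lo else lo
                site_freq = np.full(n_samples, q)
            doses = rng.binomial(2, np.clip(site_freq, 0, 1)).astype(float)
            if damaging:
                planted_mask = np.array([
                    truth.planted[s] is not None
                    and module_of_gene.get(gene) == truth.planted[s]
                    for s in sample_ids
                ])
                if planted_mask.any():
                    hit = rng.uniform(size=n_samples) < cfg.signal_carrier_p
                    doses = np.where(planted_mask & hit, np.maximum(doses, 1), doses)
            rows.append({
                "Chr": "1",
                "Pos": pos_counter * 1000,
                "Gene": gene,
                "ExonicFunc": "nonsynonymous SNV",
                **annot,
                "DP": int(rng.integers(20, 80)),
                "QUAL": float(rng.uniform(50, 500)),
                "QD": float(rng.uniform(2, 20)),
                "FS": float(rng.uniform(0, 30)),
                "AltMappings": 1,
            })
            for s, d in zip(sample_ids, doses):
                geno_cols[s].append(int(d))

    df = pd.concat([pd.DataFrame(rows), pd.DataFrame(geno_cols)], axis=1)
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "group": [truth.sample_groups[s] for s in sample_ids],
    })
    return df, sheet
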