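"""Model/Results interface for the multi-sample PPI clustering analysis.

:class:`NetworkClusterModel` holds the data (per-sample seed genes or a raw
variant table plus sample sheet) and the analysis configuration; ``fit()``
runs network construction, Jaccard similarity, UPGMA and branch enrichment,
and returns a :class:`NetworkClusterResults` carrying the dendrogram, the
significant clusters with their layered networks and unique genes, and a
``summary()`` table.  Separation testing between the fitted clusters hangs
off the results object.

Example
-------
>>> from ppiclust import simulate, NetworkClusterModel
>>> cfg = simulate.SimConfig(rng_seed=1)
>>> g, modules = simulate.simulate_interactome(cfg)
>>> seeds, truth = simulate.simulate_cohort_seeds(g, modules, cfg)
>>> res = NetworkClusterModel(seeds, g).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import clustering, separation as sep
from .clustering import ClusterResult, Dendrogram
from .interactome import Interactome
from .networks import SampleNetwork, build_sample_network, write_network_tsv
from .variants import FilterThresholds, SampleSeedSet, seed_sets_from_variants

logger = logging.getLogger(__name__)


class NetworkClusterModel:
    """Multi-sample PPI network clustering of a case/control cohort.

    Parameters
    ----------
    seed_sets
        Per-sample ranked seed genes with group labels.
    interactome
        Reference PPI graph on which subnetworks are built.
    max_path_length
        1 keeps only direct seed-seed edges; 2 (default) additionally connects
        seed pairs through every shared intermediary ("imputed") protein.
    alpha, min_size
        Branch significance threshold (raw one-sided Fisher exact p) and the
        minimum reported cluster size.
    bonferroni
        Divide alpha by the number of internal branches (off by default,
        matching the raw-p reporting convention).
    """

    def __init__(
        self,
        seed_sets: Sequence[SampleSeedSet],
        interactome: Interactome,
        *,
        max_path_length: int = 2,
        alpha: float = 0.001,
        min_size: int = 3,
        bonferroni: bool = False,
    ):
        ids = [s.sample_id for s in seed_sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in seed sets")
        self.seed_sets = sorted(seed_sets, key=lambda s: s.sample_id)
        self.interactome = interactome
        self.max_path_length = max_path_length
        self.alpha = alpha
        self.min_size = min_size
        self.bonferroni = bonferroni

    @classmethod
    def from_variant_table(
        cls,
        variants: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        interactome: Interactome,
        *,
        thresholds: FilterThresholds = FilterThresholds(),
        K: int = 30,
        association_method: str = "trend_pca_adjusted",
        n_pcs: int = 10,
        **kwargs,
    ) -> "NetworkClusterModel":
        """Build the model from an annotated variant table (runs the variant stage)."""
        seed_sets, counts = seed_sets_from_variants(
            variants, sample_sheet,
            thresholds=thresholds, K=K, method=association_method, n_pcs=n_pcs,
        )
        model = cls(seed_sets, interactome, **kwargs)
        model.variant_stage_counts = counts
        return model

    def fit(self) -> "NetworkClusterResults":
        """Run networks -> similarity -> UPGMA -> branch enrichment -> clusters."""
        networks = [
            build_sample_network(s, self.interactome, self.max_path_length)
            for s in self.seed_sets
        ]
        similarity, excluded = clustering.similarity_matrix(networks)
        if len(similarity) < 2:
            raise ValueError("need at least two samples with nonempty networks")
        distance = 1.0 - similarity
        dend = clustering.upgma(distance)
        groups = {s.sample_id: s.group for s in self.seed_sets}
        dend.annotate(groups)
        clusters = clustering.significant_clusters(
            dend, alpha=self.alpha, min_size=self.min_size, bonferroni=self.bonferroni
        )
        nets_by_id = {n.sample_id: n for n in networks}
        for cl in clusters:
            member_nets = [nets_by_id[s] for s in cl.sample_ids]
            cl.layered = clustering.layered_network(member_nets)
            cl.seed_union = frozenset().union(*(n.seed_nodes for n in member_nets))
        if clusters:
            uniq = clustering.unique_genes({c.label: set(c.seed_union) for c in clusters})
            for cl in clusters:
                cl.unique_genes = uniq[cl.label]
        return NetworkClusterResults(
            model=self,
            networks=networks,
            excluded_samples=excluded,
            similarity=similarity,
            dendrogram=dend,
            clusters=clusters,
        )


class NetworkClusterResults:
    """Fitted clustering of a cohort's PPI networks."""

    def __init__(
        self,
        model: NetworkClusterModel,
        networks: Sequence[SampleNetwork],
        excluded_samples: Sequence[str],
        similarity: pd.DataFrame,
        dendrogram: Dendrogram,
        clusters: Sequence[ClusterResult],
    ):
        self.model = model
        self.networks = list(networks)
        self.excluded_samples = list(excluded_samples)
        self.similarity = similarity
        self.dendrogram = dendrogram
        self.clusters = list(clusters)

    # -- derived quantities ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.networks)

    def case_dominated(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.dominant_group == "case"]

    def min_branch_p(self, dominant_group: Optional[str] = None,
                     min_size: Optional[int] = None) -> float:
        """Smallest branch enrichment p over internal dendrogram branches.

        Optionally restricted to branches dominated by one group and/or of a
        minimum size.
        """
        min_size = self.model.min_size if min_size is None else min_size
        ps = [
            node.p for node in self.dendrogram.internal_nodes()
            if node.size >= min_size
            and (dominant_group is None or node.dominant_group == dominant_group)
        ]
        return min(ps) if ps else 1.0

    def cluster_assignments(self) -> pd.DataFrame:
        """Tidy table: sample_id, group, cluster label ('' = unassigned)."""
        label_of = {}
        for c in self.clusters:
            for s in c.sample_ids:
                label_of[s] = c.label
        rows = [
            {"sample_id": s.sample_id, "group": s.group,
             "cluster": label_of.get(s.sample_id, "")}
            for s in self.model.seed_sets
        ]
        return pd.DataFrame(rows)

    def separation_between_clusters(self, use_unique_genes: bool = True) -> pd.DataFrame:
        """Pairwise separation scores s between the reported clusters.

        By default the cluster-unique seed-gene sets are compared (the inputs
        the separation analysis is defined on); ``use_unique_genes=False``
        compares the full member seed unions instead.
        """
        if len(self.clusters) < 2:
            raise ValueError("separation needs at least two reported clusters")
        sets = {
            c.label: (set(c.unique_genes) if use_unique_genes else set(c.seed_union))
            for c in self.clusters
        }
        return sep.separation_matrix(sets, sets, self.model.interactome)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary in the style of a regression results table."""
        n_cases = sum(1 for s in self.model.seed_sets if s.group == "case")
        n_controls = len(self.model.seed_sets) - n_cases
        lines = [
            "Multi-sample PPI Network Clustering Results",
            "=" * 60,
            f"Samples:               {len(self.model.seed_sets)}"
            f" ({n_cases} cases / {n_controls} controls)",
            f"Clustered (nonempty):  {self.n_samples}"
            f"   excluded empty: {len(self.excluded_samples)}",
            f"Interactome:           {self.model.interactome.n_nodes} nodes /"
            f" {self.model.interactome.n_edges} edges",
            f"Max path length:       {self.model.max_path_length}"
            f"    alpha: {self.model.alpha:g}    min size: {self.model.min_size}",
            "-" * 60,
        ]
        if self.clusters:
            lines.append(f"{'cluster':<8}{'size':>5}{'cases':>7}{'controls':>9}"
                         f"{'dominant':>10}{'Fisher p':>12}")
            for c in self.clusters:
                lines.append(
                    f"{c.label:<8}{c.size:>5}{c.n_cases:>7}{c.n_controls:>9}"
                    f"{c.dominant_group:>10}{c.p:>12.3g}"
                )
        else:
            lines.append("no significant clusters at the configured threshold")
        lines.append("-" * 60)
        for c in self.clusters:
            genes = sorted(c.unique_genes)
            shown = ", ".join(genes[:10])
            if len(genes) > 10:
                shown += f", ... (+{len(genes) - 10} more; see unique_genes.tsv)"
            lines.append(f"unique genes {c.label} ({len(genes)}): {shown}")
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        """Machine-readable stage counts and cluster table (deterministic)."""
        n_cases = sum(1 for s in self.model.seed_sets if s.group == "case")
        d = {
            "n_samples": len(self.model.seed_sets),
            "n_cases": n_cases,
            "n_controls": len(self.model.seed_sets) - n_cases,
            "n_clustered": self.n_samples,
            "excluded_samples": self.excluded_samples,
            "alpha": self.model.alpha,
            "min_size": self.model.min_size,
            "max_path_length": self.model.max_path_length,
            "n_clusters": len(self.clusters),
            "clusters": [
                {
                    "label": c.label,
                    "size": c.size,
                    "cases": c.n_cases,
                    "controls": c.n_controls,
                    "dominant_group": c.dominant_group,
                    "p": c.p,
                    "members": list(c.sample_ids),
                    "unique_genes": sorted(c.unique_genes),
                }
                for c in self.clusters
            ],
        }
        if hasattr(self.model, "variant_stage_counts"):
            d["variant_stage"] = self.model.variant_stage_counts
        return d

    def save(self, out_dir) -> Path:
        """Write all artifacts (TSV/Newick/GraphML/JSON) into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # seeds
        with open(out / "seeds.tsv", "w") as fh:
            fh.write("sample_id\tgroup\trank\tgene\tp\n")
            for s in self.model.seed_sets:
                pvals = s.pvalues if s.pvalues else ("",) * len(s.seeds)
                for rank, (gene, p) in enumerate(zip(s.seeds, pvals), start=1):
                    fh.write(f"{s.sample_id}\t{s.group}\t{rank}\t{gene}\t{p}\n")
        # per-sample networks
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for net in self.networks:
            write_network_tsv(net, net_dir / f"{net.sample_id}.tsv")
        # similarity matrix
        self.similarity.to_csv(out / "similarity.tsv", sep="\t")
        # dendrogram
        (out / "dendrogram.nwk").write_text(self.dendrogram.to_newick() + "\n")
        # cluster report
        self.cluster_assignments().to_csv(out / "clusters.tsv", sep="\t", index=False)
        # layered networks + unique genes
        with open(out / "unique_genes.tsv", "w") as fh:
            fh.write("gene\tcluster\n")
            for c in self.clusters:
                for g in sorted(c.unique_genes):
                    fh.write(f"{g}\t{c.label}\n")
        for c in self.clusters:
            if c.layered is not None:
                nx.write_graphml(c.layered, out / f"layered_{c.label}.graphml")
        # separation between clusters (when >= 2)
        if len(self.clusters) >= 2:
            mat = self.separation_between_clusters()
            mat = mat.assign(min_per_row=sep.flag_row_minima(mat))
            mat.to_csv(out / "separation.tsv", sep="\t")
        # summary
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out
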