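"""Per-sample PPI subnetworks: seed genes connected directly or via one intermediary.

Each sample's network is built from its seed genes mapped onto the reference
interactome.  Two seeds that are interactome neighbours contribute that edge;
two seeds at hop distance 2 contribute *every* length-2 path between them —
each shared neighbour becomes an "imputed" node carrying both edges (taking
all qualifying intermediaries, rather than one arbitrary shortest path, keeps
the output reproducible and independent of traversal order).  Seeds farther
than the maximum path length from every other seed are dropped from the node
set, so they cannot dilute the Jaccard similarity, but are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Union

import networkx as nx

from .interactome import Interactome
from .variants import SampleSeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleNetwork:
    """One sample's seed + imputed subnetwork of the interactome."""

    sample_id: str
    group: str
    seed_nodes: frozenset[str]
    imputed_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # canonically sorted pairs
    dropped_seeds: tuple[str, ...]  # absent from interactome, or unconnected

    @property
    def nodes(self) -> frozenset[str]:
        return self.seed_nodes | self.imputed_nodes

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def to_graph(self) -> nx.Graph:
        """Materialise as a networkx graph with a ``role`` node attribute."""
        g = nx.Graph()
        for n in self.seed_nodes:
            g.add_node(n, role="seed")
        for n in self.imputed_nodes:
            g.add_node(n, role="imputed")
        g.add_edges_from(self.edges)
        return g


def _edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_sample_network(
    seeds: Union[SampleSeedSet, Iterable[str]],
    interactome: Interactome,
    max_path_length: int = 2,
    sample_id: str = "",
    group: str = "",
) -> SampleNetwork:
    """Construct a sample's PPI subnetwork from its seed genes.

    Every unordered seed pair at hop distance 1 contributes its edge; at
    distance 2 (if ``max_path_length == 2``) every shared non-seed neighbour
    is added as an imputed node together with both of its edges.  Seeds absent
    from the interactome, or farther than ``max_path_length`` from every other
    seed, end up in ``dropped_seeds``.
    """
    if max_path_length not in (1, 2):
        raise ValueError("max_path_length must be 1 or 2")
    if isinstance(seeds, SampleSeedSet):
        sample_id = sample_id or seeds.sample_id
        group = group or seeds.group
        seed_list = list(seeds.seeds)
    else:
        seed_list = list(seeds)
    seed_list = [s.upper() for s in seed_list]
    if not seed_list:
        logger.warning("sample %s: empty seed set -> empty network", sample_id)
        return SampleNetwork(sample_id, group, frozenset(), frozenset(), frozenset(), ())

    present = [s for s in dict.fromkeys(seed_list) if s in interactome]
    absent = [s for s in dict.fromkeys(seed_list) if s not in interactome]
    seed_set = set(present)

    edges: set[tuple[str, str]] = set()
    imputed: set[str] = set()
    adj = {s: interactome.neighbors(s) for s in present}
    for a, b in combinations(present, 2):
        if b in adj[a]:
            edges.add(_edge(a, b))
        elif max_path_length >= 2:
            for c in (adj[a] & adj[b]) - seed_set:
                imputed.add(c)
                edges.add(_edge(a, c))
                edges.add(_edge(c, b))

    connected = {n for e in edges for n in e}
    retained_seeds = seed_set & connected
    unconnected = sorted(seed_set - connected)
    dropped = tuple(sorted(absent) + unconnected)
    if not retained_seeds:
        logger.warning("sample %s: no connected seeds -> empty network", sample_id)
        return SampleNetwork(sample_id, group, frozenset(), frozenset(), frozenset(), dropped)
    return SampleNetwork(
        sample_id, group,
        frozenset(retained_seeds), frozenset(imputed), frozenset(edges), dropped,
    )


def write_network_tsv(net: SampleNetwork, path) -> None:
    """Write the edge list as a 3-column TSV: node1, node2, provenance."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tprovenance\n")
        for a, b in sorted(net.edges):
            kinds = ("seed" if a in net.seed_nodes else "imputed",
                     "seed" if b in net.seed_nodes else "imputed")
            prov = "seed-seed" if kinds == ("seed", "seed") else "seed-imputed"
            fh.write(f"{a}\t{b}\t{prov}\n")


def write_node_table(net: SampleNetwork, path) -> None:
    """Write the node attribute table: symbol, role."""
    with open(path, "w") as fh:
        fh.write("symbol\trole\n")
        for n in sorted(net.nodes):
            fh.write(f"{n}\t{'seed' if n in net.seed_nodes else 'imputed'}\n")
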