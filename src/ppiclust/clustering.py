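"""Patient clustering on network similarity: Jaccard matrix, UPGMA, Fisher branches.

Samples are compared by the Jaccard index of their network node sets
(seed + imputed); 1 - Jaccard is the clustering distance.  UPGMA
(average-linkage with cluster-size-weighted means) builds the dendrogram,
every internal branch gets a one-sided Fisher exact (hypergeometric)
enrichment p-value for its dominant group, and the reported clusters are the
maximal significant branches.  Samples are ordered by sample id before
clustering so results are invariant to input row order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import SampleNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Similarity

def jaccard(a: Union[SampleNetwork, set], b: Union[SampleNetwork, set]) -> float:
    """Jaccard index of two node sets (both empty -> 0 by convention)."""
    sa = a.nodes if isinstance(a, SampleNetwork) else set(a)
    sb = b.nodes if isinstance(b, SampleNetwork) else set(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def similarity_matrix(
    networks: Sequence[SampleNetwork],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Jaccard similarity between sample networks.

    Samples with empty networks are excluded (they carry no network
    information) and returned separately.  Rows/columns are ordered by
    sample id, making the matrix independent of input order.

    Returns ``(similarity DataFrame, excluded sample ids)``.
    """
    nonempty = sorted((n for n in networks if not n.is_empty), key=lambda n: n.sample_id)
    excluded = sorted(n.sample_id for n in networks if n.is_empty)
    if excluded:
        logger.warning("excluding %d sample(s) with empty networks: %s",
                       len(excluded), ", ".join(excluded))
    ids = [n.sample_id for n in nonempty]
    node_sets = [n.nodes for n in nonempty]
    m = len(ids)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = jaccard(node_sets[i], node_sets[j])
    return pd.DataFrame(S, index=ids, columns=ids), excluded


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class DendrogramNode:
    """A node of the UPGMA tree; leaves carry one sample, internal nodes two children."""

    height: float
    members: tuple[str, ...]  # sample ids under this node
    left: Optional["DendrogramNode"] = None
    right: Optional["DendrogramNode"] = None
    # branch annotations (filled by annotate())
    n_cases: int = 0
    n_controls: int = 0
    dominant_group: str = ""
    p: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Dendrogram:
    """UPGMA merge tree over samples, with per-branch enrichment annotations."""

    root: DendrogramNode
    leaf_ids: tuple[str, ...]
    groups: dict[str, str] = field(default_factory=dict)

    def internal_nodes(self) -> list[DendrogramNode]:
        out: list[DendrogramNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend((node.left, node.right))
        return out

    def annotate(self, groups: Mapping[str, str]) -> None:
        """Attach case/control counts and branch Fisher p-values."""
        groups = {k: v for k, v in groups.items()}
        missing = [s for s in self.leaf_ids if s not in groups]
        if missing:
            raise KeyError(f"no group assignment for sample(s): {missing}")
        self.groups = {s: groups[s] for s in self.leaf_ids}
        total_cases = sum(1 for s in self.leaf_ids if self.groups[s] == "case")
        total_controls = len(self.leaf_ids) - total_cases

        def _visit(node: DendrogramNode) -> None:
            node.n_cases = sum(1 for s in node.members if self.groups[s] == "case")
            node.n_controls = node.size - node.n_cases
            node.p, node.dominant_group = branch_fisher(
                node.n_cases, node.n_controls, total_cases, total_controls
            )
            if not node.is_leaf:
                _visit(node.left)
                _visit(node.right)

        _visit(self.root)

    def to_newick(self) -> str:
        """Newick string with branch lengths and internal labels 'members|cases|controls|p'."""

        def _fmt(node: DendrogramNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.members[0]}:{blen:.6g}"
            label = f"'{node.size}|{node.n_cases}|{node.n_controls}|{node.p:.4g}'"
            kids = ",".join(_fmt(c, node.height) for c in (node.left, node.right))
            return f"({kids}){label}:{blen:.6g}"

        r = self.root
        kids = ",".join(_fmt(c, r.height) for c in (r.left, r.right))
        label = f"'{r.size}|{r.n_cases}|{r.n_controls}|{r.p:.4g}'"
        return f"({kids}){label};"


def upgma(distance: Union[np.ndarray, pd.DataFrame], labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """UPGMA (size-weighted average-linkage) agglomeration of a distance matrix.

    Merge heights are half the merge distance (so leaf-to-ancestor path length
    equals half the average pairwise distance, the ultrametric convention).
    Ties are broken deterministically by the lowest-index pair in the current
    cluster ordering, and a merged cluster keeps the lower of its parents'
    indices.
    """
    if isinstance(distance, pd.DataFrame):
        if labels is None:
            labels = list(distance.index)
        distance = distance.to_numpy(dtype=float)
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("distance must be a square matrix with n >= 2")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = [str(x) for x in labels]

    nodes: list[DendrogramNode] = [DendrogramNode(0.0, (lab,)) for lab in labels]
    sizes = np.ones(n)
    W = D.copy()
    np.fill_diagonal(W, np.inf)
    active = list(range(n))  # positions into W rows/cols

    while len(active) > 1:
        sub = W[np.ix_(active, active)]
        sub = np.triu(sub, k=1) + np.tril(np.full_like(sub, np.inf))
        flat = np.argmin(sub)  # row-major: lowest-index pair wins ties
        i_loc, j_loc = divmod(flat, sub.shape[1])
        i, j = active[i_loc], active[j_loc]
        dij = W[i, j]
        merged = DendrogramNode(
            height=dij / 2.0,
            members=nodes[i].members + nodes[j].members,
            left=nodes[i],
            right=nodes[j],
        )
        si, sj = sizes[i], sizes[j]
        # Lance-Williams update for arithmetic-mean linkage
        new_row = (si * W[i, :] + sj * W[j, :]) / (si + sj)
        W[i, :] = new_row
        W[:, i] = new_row
        W[i, i] = np.inf
        sizes[i] = si + sj
        nodes[i] = merged
        active.remove(j)

    root = nodes[active[0]]
    return Dendrogram(root=root, leaf_ids=tuple(labels))


# ---------------------------------------------------------------------------
# Branch enrichment

def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= max(0, n - (N - K)):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def branch_fisher(
    branch_cases: int, branch_controls: int, total_cases: int, total_controls: int
) -> tuple[float, str]:
    """One-sided Fisher exact enrichment p for a dendrogram branch.

    The branch's *dominant* group is the one over-represented relative to its
    cohort proportion (ties favour cases); the p-value is the hypergeometric
    upper tail of observing at least the branch's count of that group, from
    the 2x2 table (in/out of branch) x (case/control).  An empty branch
    returns p = 1.
    """
    n = branch_cases + branch_controls
    N = total_cases + total_controls
    if branch_cases > total_cases or branch_controls > total_controls:
        raise ValueError("branch counts exceed cohort totals")
    if n == 0:
        return 1.0, ""
    case_excess = branch_cases * N - n * total_cases  # sign of enrichment
    if case_excess > 0:
        dominant = "case"
    elif case_excess < 0:
        dominant = "control"
    else:
        dominant = "case" if branch_cases >= branch_controls else "control"
    if dominant == "case":
        p = hypergeom_tail(branch_cases, total_cases, n, N)
    else:
        p = hypergeom_tail(branch_controls, total_controls, n, N)
    return p, dominant


# ---------------------------------------------------------------------------
# Significant clusters

@dataclass
class ClusterResult:
    """A reported (maximal significant) patient cluster."""

    label: str
    sample_ids: tuple[str, ...]
    n_cases: int
    n_controls: int
    dominant_group: str
    p: float
    seed_union: frozenset[str] = frozenset()
    unique_genes: frozenset[str] = frozenset()
    layered: Optional[nx.Graph] = None

    @property
    def size(self) -> int:
        return len(self.sample_ids)


def significant_clusters(
    dend: Dendrogram,
    alpha: float = 0.001,
    min_size: int = 3,
    bonferroni: bool = False,
) -> list[ClusterResult]:
    """Extract the maximal significant branches of an annotated dendrogram.

    A branch is reported when p < ``alpha``, its size is >= ``min_size`` and
    no ancestor is itself reported; reported clusters are therefore disjoint.
    ``bonferroni=True`` divides alpha by the number of internal branches.
    Labels A, B, ... are assigned in descending size (ties by first sample id).
    """
    if not dend.groups:
        raise ValueError("dendrogram must be annotated with groups first")
    threshold = alpha / len(dend.internal_nodes()) if bonferroni else alpha

    hits: list[DendrogramNode] = []

    def _visit(node: DendrogramNode) -> None:
        if node.size >= min_size and node.p < threshold:
            hits.append(node)
            return  # maximality: do not descend into a significant branch
        if not node.is_leaf:
            _visit(node.left)
            _visit(node.right)

    _visit(dend.root)
    hits.sort(key=lambda nd: (-nd.size, min(nd.members)))
    out = []
    for label, node in zip(_labels(), hits):
        out.append(ClusterResult(
            label=label,
            sample_ids=tuple(sorted(node.members)),
            n_cases=node.n_cases,
            n_controls=node.n_controls,
            dominant_group=node.dominant_group,
            p=node.p,
        ))
    return out


def _labels():
    import itertools, string
    for size in itertools.count(1):
        for tup in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(tup)


# ---------------------------------------------------------------------------
# Layered networks & unique genes

def layered_network(networks: Sequence[SampleNetwork]) -> nx.Graph:
    """Annotated union of a cluster's member networks.

    Node attributes: ``role`` ('seed' if the node is a seed for any member,
    else 'imputed'), ``group_membership`` ('case' / 'control' / 'both',
    from the groups of contributing members), ``support`` (number of members
    whose network contains the node).  Edge attribute ``support`` counts the
    members containing the edge.
    """
    nets = [n for n in networks if not n.is_empty]
    if not nets:
        raise ValueError("layered_network needs at least one nonempty member network")
    g = nx.Graph()
    for net in nets:
        for node in net.nodes:
            role = "seed" if node in net.seed_nodes else "imputed"
            if node in g:
                data = g.nodes[node]
                data["support"] += 1
                data["_groups"].add(net.group)
                if role == "seed":
                    data["role"] = "seed"  # seed-in-any-member takes precedence
            else:
                g.add_node(node, role=role, support=1, _groups={net.group})
        for a, b in net.edges:
            if g.has_edge(a, b):
                g[a][b]["support"] += 1
            else:
                g.add_edge(a, b, support=1)
    for node, data in g.nodes(data=True):
        groups = data.pop("_groups")
        data["group_membership"] = "both" if len(groups) > 1 else next(iter(groups))
    return g


def unique_genes(seed_unions: Mapping[str, set]) -> dict[str, frozenset[str]]:
    """Per-cluster seed genes not found in any other cluster's seed union.

    With a single cluster its full seed union is returned (with a warning).
    Outputs are pairwise disjoint by construction.
    """
    labels = list(seed_unions)
    if len(labels) < 2:
        logger.warning("unique_genes called with a single cluster; returning full seed union")
        return {lab: frozenset(seed_unions[lab]) for lab in labels}
    out = {}
    for lab in labels:
        others: set = set()
        for other in labels:
            if other != lab:
                others |= set(seed_unions[other])
        out[lab] = frozenset(set(seed_unions[lab]) - others)
    return out
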