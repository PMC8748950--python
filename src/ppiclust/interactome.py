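"""Reference protein–protein interactome: loading, filtering, and distance queries.

The interactome is an undirected graph over gene symbols with STRING-style
integer confidence scores (0–1000) on the edges.  Confidence is used only to
decide which edges enter the graph; all path-length queries downstream are
unweighted hop counts, because "connected via a single intermediary protein"
is a hop-count notion (Dijkstra on unit weights reduces to BFS).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: STRING "high confidence" cutoff; the default edge-inclusion threshold.
DEFAULT_MIN_CONFIDENCE = 700


class InteractomeParseError(ValueError):
    """Raised when an edge-list or symbol-map file cannot be parsed."""


class Interactome:
    """Undirected weighted PPI graph over uppercase gene symbols.

    Thin wrapper around :class:`networkx.Graph` providing the queries the
    pipeline needs (membership, neighbors, hop distances) with symbols
    normalised to uppercase so matching is case-insensitive everywhere.
    """

    def __init__(self, graph: nx.Graph):
        self._g = graph

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "Interactome":
        """Build from ``(a, b, confidence)`` triples; keeps max confidence on duplicates."""
        g = nx.Graph()
        for a, b, conf in edges:
            a, b = a.upper(), b.upper()
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        return cls(g)

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._g

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a.upper(), b.upper())

    def neighbors(self, symbol: str) -> frozenset[str]:
        s = symbol.upper()
        if s not in self._g:
            raise KeyError(f"unknown gene symbol: {symbol!r}")
        return frozenset(self._g.neighbors(s))

    def confidence(self, a: str, b: str) -> float:
        return self._g[a.upper()][b.upper()]["confidence"]

    # -- distances ---------------------------------------------------------

    def distance(self, a: str, b: str) -> float:
        """Unweighted hop count of the shortest path; ``inf`` if disconnected."""
        a, b = a.upper(), b.upper()
        for s in (a, b):
            if s not in self._g:
                raise KeyError(f"unknown gene symbol: {s!r}")
        if a == b:
            return 0
        try:
            return nx.shortest_path_length(self._g, a, b)
        except nx.NetworkXNoPath:
            return math.inf

    def distances_from(self, source: str, cutoff: Optional[int] = None) -> dict[str, int]:
        """Hop distances from ``source`` to every reachable node (BFS)."""
        s = source.upper()
        if s not in self._g:
            raise KeyError(f"unknown gene symbol: {source!r}")
        return dict(nx.single_source_shortest_path_length(self._g, s, cutoff=cutoff))


def shortest_hop_distance(g: Interactome, a: str, b: str) -> float:
    """Hop count between two symbols in ``g``; 0 iff ``a == b``, ``inf`` if no path."""
    return g.distance(a, b)


def read_symbol_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping external protein identifiers to gene symbols.

    Many-to-one mappings are permitted; target symbols are uppercased and must
    be non-empty.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[1].strip():
                raise InteractomeParseError(
                    f"{path}: line {lineno}: expected 'identifier<TAB>symbol'"
                )
            mapping[parts[0].strip()] = parts[1].strip().upper()
    return mapping


def read_interactome(
    path,
    min_confidence: int = DEFAULT_MIN_CONFIDENCE,
    symbol_map: Optional[Mapping[str, str]] = None,
) -> Interactome:
    """Load a STRING-dialect edge list, keeping edges with confidence >= threshold.

    The file is whitespace- or tab-separated with columns
    ``protein1 protein2 [combined_score]``; an optional single header line is
    detected by a non-numeric score field on line 1.  A missing score column
    means full confidence (1000).  Duplicate edges (either orientation)
    collapse to the maximum confidence; self-loops are dropped.

    Parameters
    ----------
    min_confidence
        Edge-inclusion threshold on the 0–1000 STRING combined_score scale.
    symbol_map
        Optional identifier→symbol mapping applied before graph construction;
        edges with unmapped identifiers are dropped (and counted).

    Raises
    ------
    InteractomeParseError
        On a malformed line (with its line number).
    ValueError
        If no edges survive filtering.
    """
    if not 0 <= min_confidence <= 1000:
        raise ValueError(f"min_confidence must be in [0, 1000], got {min_confidence}")

    edges: list[tuple[str, str, float]] = []
    n_below, n_unmapped, n_selfloops = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise InteractomeParseError(
                    f"{path}: line {lineno}: expected at least 2 columns"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    conf = float(parts[2])
                except ValueError:
                    if lineno == 1:  # header line
                        continue
                    raise InteractomeParseError(
                        f"{path}: line {lineno}: non-numeric confidence {parts[2]!r}"
                    ) from None
                if not 0 <= conf <= 1000:
                    raise InteractomeParseError(
                        f"{path}: line {lineno}: confidence {conf} outside [0, 1000]"
                    )
            else:
                conf = 1000.0
            if symbol_map is not None:
                if a not in symbol_map or b not in symbol_map:
                    n_unmapped += 1
                    continue
                a, b = symbol_map[a], symbol_map[b]
            a, b = a.upper(), b.upper()
            if a == b:
                n_selfloops += 1
                continue
            if conf < min_confidence:
                n_below += 1
                continue
            edges.append((a, b, conf))

    logger.info(
        "read_interactome: kept %d edge records; dropped %d below confidence %d, "
        "%d with unmapped identifiers, %d self-loops",
        len(edges), n_below, min_confidence, n_unmapped, n_selfloops,
    )
    if not edges:
        raise ValueError(
            f"{path}: no edges remain at min_confidence={min_confidence}"
        )
    return Interactome.from_edges(edges)
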