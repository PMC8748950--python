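"""Interactome separation score between two gene sets (network-medicine s_AB).

For gene sets A and B on an interactome, the within-set distance of a gene is
the hop distance to its nearest *other* member of the same set; the
between-set distance of a gene is the hop distance to the nearest member of
the opposite set (0 for a gene shared by both sets).  With d_AA, d_BB the
within means and d_AB the mean of the between distances taken over the genes
of A and the genes of B,

    s_AB = d_AB - (d_AA + d_BB) / 2.

A negative score means the two sets occupy overlapping neighbourhoods of the
interactome; the more negative, the greater the overlap.  Genes absent from
the interactome, and nearest-neighbour distances that are unreachable
(different connected component), are excluded from the means and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeparationResult:
    s: float
    mean_within_a: float
    mean_within_b: float
    mean_between: float
    n_dropped_a: int  # genes absent from the interactome
    n_dropped_b: int
    n_unreachable: int  # nearest-neighbour distances excluded as infinite


def _nearest(dist: Mapping[str, int], targets: Iterable[str], exclude_self: str = "") -> float:
    best = math.inf
    for t in targets:
        if t == exclude_self:
            continue
        d = dist.get(t)
        if d is not None and d < best:
            best = d
    return best


def separation(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    interactome: Interactome,
) -> SeparationResult:
    """Separation score s between two gene sets on the interactome.

    Each retained set must contain at least two interactome genes, otherwise
    a ``ValueError('degenerate set ...')`` is raised.
    """
    a_all = {g.upper() for g in genes_a}
    b_all = {g.upper() for g in genes_b}
    A = {g for g in a_all if g in interactome}
    B = {g for g in b_all if g in interactome}
    n_dropped_a = len(a_all) - len(A)
    n_dropped_b = len(b_all) - len(B)
    if len(A) < 2 or len(B) < 2:
        raise ValueError(
            f"degenerate set: need >= 2 interactome genes per set "
            f"(got |A|={len(A)}, |B|={len(B)})"
        )

    dist = {g: interactome.distances_from(g) for g in A | B}
    n_unreachable = 0

    def _mean(values: list[float]) -> float:
        nonlocal n_unreachable
        finite = [v for v in values if math.isfinite(v)]
        n_unreachable += len(values) - len(finite)
        return float(np.mean(finite)) if finite else math.nan

    within_a = _mean([_nearest(dist[g], A, exclude_self=g) for g in A])
    within_b = _mean([_nearest(dist[g], B, exclude_self=g) for g in B])
    between = _mean(
        [_nearest(dist[g], B) for g in A] + [_nearest(dist[g], A) for g in B]
    )
    if n_unreachable:
        logger.info("separation: excluded %d unreachable nearest-neighbour distances",
                    n_unreachable)
    s = between - (within_a + within_b) / 2.0
    return SeparationResult(
        s=float(s),
        mean_within_a=within_a,
        mean_within_b=within_b,
        mean_between=between,
        n_dropped_a=n_dropped_a,
        n_dropped_b=n_dropped_b,
        n_unreachable=n_unreachable,
    )


def separation_matrix(
    sets_x: Mapping[str, Iterable[str]],
    sets_y: Mapping[str, Iterable[str]],
    interactome: Interactome,
) -> pd.DataFrame:
    """Separation score s for every X x Y pair of labelled gene sets.

    Failed pairs (degenerate sets) become NaN rather than fabricated values.
    Use :func:`flag_row_minima` to mark each row's most-negative ("most
    similar") entry.
    """
    rows = {}
    for xl, xg in sets_x.items():
        row = {}
        for yl, yg in sets_y.items():
            try:
                row[yl] = separation(xg, yg, interactome).s
            except ValueError as exc:
                logger.warning("separation %s vs %s failed: %s", xl, yl, exc)
                row[yl] = math.nan
        rows[xl] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def flag_row_minima(matrix: pd.DataFrame) -> pd.Series:
    """Label of the most-negative (most similar) column per row; NaN rows give ''."""
    out = {}
    for idx, row in matrix.iterrows():
        out[idx] = "" if row.isna().all() else row.idxmin()
    return pd.Series(out, name="min_per_row")
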