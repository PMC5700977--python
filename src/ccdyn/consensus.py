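"""k-consensus connectomes and their growth dynamics.

Given an ensemble of ``n`` subject braingraphs over one atlas, an edge is
*k-frequent* if it is present in at least ``k`` of the subject graphs, and the
*k-consensus connectome* is the graph of all k-frequent edges.  Decreasing
``k`` from ``n`` down to 1 relaxes the inclusion condition, so the consensus
connectomes form a nested, growing sequence — the consensus connectome
dynamics (CCD).  Step ``i`` of the dynamics (``i = 1..n``) corresponds to the
``(n+1-i)``-consensus connectome, so step 1 is the strictest consensus
(edges present in every subject) and step ``n`` the union of all edges.

An edge newly appearing at parameter ``k`` is *isolated* if it shares no
endpoint with any other edge of the k-consensus connectome.  The scarcity of
isolated edges is the quantitative signature of the dynamics: new edges
overwhelmingly attach to the already-present structure rather than landing in
empty territory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import AtlasNodeSet, BrainGraphEnsemble

__all__ = [
    "EdgeFrequencyTable",
    "CCDTrajectory",
    "AppearanceOrder",
    "edge_frequencies",
    "k_consensus",
    "new_isolated_count",
    "ccd_trajectory",
    "appearance_orders",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class EdgeFrequencyTable:
    """Per-edge count of subject graphs containing it.

    Only edges with frequency >= 1 are stored; absent pairs implicitly have
    frequency 0.  This table is the sufficient statistic for every
    k-consensus computation.
    """

    atlas: AtlasNodeSet
    n: int
    freq: Mapping[Edge, int]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("subject count n must be >= 1")
        for e, f in self.freq.items():
            if not 1 <= f <= self.n:
                raise ValueError(f"frequency of {e} is {f}, outside 1..{self.n}")
            if e[0] == e[1]:
                raise ValueError(f"self-loop {e} in frequency table")

    @property
    def n_stored_edges(self) -> int:
        return len(self.freq)

    def stored_vertices(self) -> set[str]:
        """Vertices with at least one stored incident edge."""
        return {x for e in self.freq for x in e}


@dataclass(frozen=True)
class CCDTrajectory:
    """Per-step summary of the growing consensus sequence.

    All five lists have length ``n``; entry ``i-1`` describes step ``i``,
    i.e. the ``(n+1-i)``-consensus connectome.
    """

    n: int
    k: tuple[int, ...]
    edge_count: tuple[int, ...]
    new_edges: tuple[int, ...]
    new_isolated: tuple[int, ...]
    cumulative_isolated: tuple[int, ...]

    @property
    def steps(self) -> tuple[int, ...]:
        return tuple(range(1, self.n + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "k": self.k,
                "edge_count": self.edge_count,
                "new_edges": self.new_edges,
                "new_isolated": self.new_isolated,
                "cumulative_isolated": self.cumulative_isolated,
            }
        )


@dataclass(frozen=True)
class AppearanceOrder:
    """Step at which each edge or vertex first enters the consensus sequence.

    ``step`` maps items to their appearance step in ``1..n``; items absent
    from every subject graph never appear and are simply not in the map.
    An edge of frequency ``f >= 1`` appears at step ``n + 1 - f``; a vertex
    appears with the earliest of its incident edges.
    """

    kind: str  # "edge" | "vertex"
    n: int
    step: Mapping[object, int]

    def step_of(self, item) -> int | None:
        """Appearance step, or None for items that never appear."""
        return self.step.get(item)


def edge_frequencies(ensemble: BrainGraphEnsemble) -> EdgeFrequencyTable:
    """Count, for every edge, the number of subject graphs containing it."""
    counts: Counter[Edge] = Counter()
    for g in ensemble.graphs:
        counts.update(g.edges)
    return EdgeFrequencyTable(ensemble.atlas, ensemble.n, dict(counts))


def _check_k(table: EdgeFrequencyTable, k: int) -> None:
    if not 1 <= k <= table.n:
        raise ValueError(f"k={k} out of range 1..{table.n}")


def k_consensus(table: EdgeFrequencyTable, k: int) -> set[Edge]:
    """The set of k-frequent edges: every edge present in >= k subjects."""
    _check_k(table, k)
    return {e for e, f in table.freq.items() if f >= k}


def new_isolated_count(table: EdgeFrequencyTable, k: int) -> int:
    """Number of isolated edges newly appearing in the k-consensus connectome.

    An edge qualifies if (a) it is in the k-consensus but not the
    (k+1)-consensus connectome (for ``k = n`` the predecessor is the empty
    graph, so every edge of the n-consensus is new), and (b) neither of its
    endpoints touches any other edge of the *full* k-consensus graph — in
    particular two new edges appearing at the same step that share a vertex
    are not isolated.
    """
    _check_k(table, k)
    degree: Counter[str] = Counter()
    new_edges = []
    for e, f in table.freq.items():
        if f >= k:
            degree[e[0]] += 1
            degree[e[1]] += 1
            if f == k:  # in k-consensus but not (k+1)-consensus
                new_edges.append(e)
    return sum(1 for u, v in new_edges if degree[u] == 1 and degree[v] == 1)


def ccd_trajectory(table: EdgeFrequencyTable) -> CCDTrajectory:
    """Compute the full consensus-growth trajectory of a frequency table.

    Step ``i`` records the size of the ``(n+1-i)``-consensus connectome, the
    edges new at that step, how many of them are isolated, and the running
    total of isolated edges.
    """
    n = table.n
    # Edges grouped by frequency; walking k = n..1 adds group k at step n+1-k.
    by_freq: dict[int, list[Edge]] = {}
    for e, f in table.freq.items():
        by_freq.setdefault(f, []).append(e)

    degree: Counter[str] = Counter()
    ks, edge_counts, news, isos, cums = [], [], [], [], []
    total = 0
    cum_iso = 0
    for k in range(n, 0, -1):
        added = by_freq.get(k, [])
        for u, v in added:
            degree[u] += 1
            degree[v] += 1
        total += len(added)
        iso = sum(1 for u, v in added if degree[u] == 1 and degree[v] == 1)
        cum_iso += iso
        ks.append(k)
        edge_counts.append(total)
        news.append(len(added))
        isos.append(iso)
        cums.append(cum_iso)
    return CCDTrajectory(
        n, tuple(ks), tuple(edge_counts), tuple(news), tuple(isos), tuple(cums)
    )


def appearance_orders(
    table: EdgeFrequencyTable,
) -> tuple[AppearanceOrder, AppearanceOrder]:
    """Appearance steps of edges and vertices in the consensus sequence.

    Edge of frequency ``f`` -> step ``n+1-f``.  Vertex -> minimum step over
    its stored incident edges.  Items with no presence in any subject are
    omitted (they never appear).
    """
    n = table.n
    edge_step = {e: n + 1 - f for e, f in table.freq.items()}
    vertex_step: dict[str, int] = {}
    for (u, v), s in edge_step.items():
        for x in (u, v):
            if x not in vertex_step or s < vertex_step[x]:
                vertex_step[x] = s
    return (
        AppearanceOrder("edge", n, edge_step),
        AppearanceOrder("vertex", n, vertex_step),
    )
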