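"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ccdyn import (
    AtlasNodeSet,
    BrainGraphEnsemble,
    EdgeFrequencyTable,
    SubjectGraph,
)


@pytest.fixture
def toy_ensemble() -> BrainGraphEnsemble:
    """Three subjects over {a, b, c, d}: frequencies ab=3, bc=1, cd=1."""
    atlas = AtlasNodeSet(("a", "b", "c", "d"))
    graphs = (
        SubjectGraph.from_pairs("s1", [("a", "b"), ("b", "c")]),
        SubjectGraph.from_pairs("s2", [("a", "b")]),
        SubjectGraph.from_pairs("s3", [("a", "b"), ("c", "d")]),
    )
    return BrainGraphEnsemble(atlas, graphs)


@pytest.fixture
def toy_table(toy_ensemble) -> EdgeFrequencyTable:
    from ccdyn import edge_frequencies

    return edge_frequencies(toy_ensemble)


def random_table(
    rng: np.random.Generator, max_nodes: int = 12, max_subjects: int = 6
) -> EdgeFrequencyTable:
    """A random small frequency table for property checks."""
    N = int(rng.integers(2, max_nodes + 1))
    n = int(rng.integers(1, max_subjects + 1))
    labels = tuple(chr(ord("a") + i) for i in range(N))
    pairs = [(labels[i], labels[j]) for i in range(N) for j in range(i + 1, N)]
    freq = {}
    for e in pairs:
        if rng.random() < 0.5:
            freq[e] = int(rng.integers(1, n + 1))
    return EdgeFrequencyTable(AtlasNodeSet(labels), n, freq)


def oracle_new_isolated(table: EdgeFrequencyTable, k: int) -> int:
    """Brute-force isolated-edge count: rebuild the k-consensus graph from
    scratch and check both membership conditions edge by edge."""
    cons = {e for e, f in table.freq.items() if f >= k}
    prev = {e for e, f in table.freq.items() if f >= k + 1}
    count = 0
    for e in cons:
        if e in prev:
            continue
        u, v = e
        touches_other = any(
            other != e and (u in other or v in other) for other in cons
        )
        if not touches_other:
            count += 1
    return count
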