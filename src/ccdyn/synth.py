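"""Synthetic braingraph ensembles with a planted developmental order.

Real consensus dynamics cannot be distributed with a test suite, so this
module generates ensembles whose statistical structure mimics it: each edge
carries a latent developmental rank, and its per-subject inclusion
probability ``q_e`` decreases with rank.  High-rank (early) edges are then
frequent across subjects and enter the consensus sequence first, so the
consensus appearance order of a sampled ensemble should recover the planted
rank — and quarter-set discordance should fall well below the 1/2 null.
Setting ``coupling = 0`` removes the rank dependence entirely (all ``q_e``
equal), giving an exchangeable null ensemble whose appearance order carries
no signal.

The planted order itself is produced by the doubly-preferential attachment
simulator, so the generator and the growth model test each other: consensus
dynamics extracted from a sampled ensemble should look DPA-grown.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dpa import DPAParams, SimulationState, initial_graph, simulate_step
from .io import AtlasNodeSet, BrainGraphEnsemble, SubjectGraph, write_graphml

__all__ = ["PlantedOrderModel", "planted_model", "sample_ensemble", "write_ensemble_dir"]

Edge = tuple[str, str]


@dataclass(frozen=True)
class PlantedOrderModel:
    """Edges in latent developmental order with per-subject probabilities.

    ``ordered_edges[r]`` is the rank-``r`` edge (rank 0 = earliest) and
    ``q[r]`` its independent per-subject inclusion probability,
    non-increasing in rank when ``coupling > 0`` and constant at
    ``(q_max + q_min) / 2`` when ``coupling = 0``.
    """

    atlas: AtlasNodeSet
    ordered_edges: tuple[Edge, ...]
    q: np.ndarray
    coupling: float

    def __post_init__(self) -> None:
        if len(self.q) != len(self.ordered_edges):
            raise ValueError("q must align with ordered_edges")
        if np.any((self.q <= 0) | (self.q > 1)):
            raise ValueError("inclusion probabilities must lie in (0, 1]")
        if self.coupling > 0 and np.any(np.diff(self.q) > 1e-12):
            raise ValueError("q must be non-increasing in rank")

    @property
    def inclusion_prob(self) -> Mapping[Edge, float]:
        return {e: float(p) for e, p in zip(self.ordered_edges, self.q)}

    @property
    def n_edges(self) -> int:
        return len(self.ordered_edges)


def _node_label(i: int, width: int) -> str:
    return f"v{i:0{width}d}"


def _dpa_arrival_order(
    N: int, n_edges: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Grow a DPA graph until ``n_edges`` edges exist; return arrival order.

    Growth parameters are internal: a brisk rate keeps the growth phase
    short, and a small C seeds occasional isolated edges so the order is not
    a single connected sweep.  Edges arriving in the same step are ranked in
    random order.
    """
    params = DPAParams(
        N=N,
        A=5.0,
        B=0.05,
        C=0.5 / (N * (N - 1) / 2),
        D=min(max(6, N // 10), N),
        steps=1,
        seed=0,
    )
    state = initial_graph(5, params.D, N, rng)
    order: list[tuple[int, int]] = []

    def record_new(before: np.ndarray) -> None:
        new = np.flatnonzero(state.present & ~before)
        rng.shuffle(new)
        iu, iv = np.triu_indices(N, k=1)
        order.extend((int(iu[i]), int(iv[i])) for i in new)

    record_new(np.zeros_like(state.present))
    guard = 0
    while len(order) < n_edges:
        before = state.present.copy()
        simulate_step(state, params, rng)
        record_new(before)
        guard += 1
        if guard > 10_000:
            raise RuntimeError("growth stalled before reaching n_edges")
    return order[:n_edges]


def planted_model(
    N: int = 100,
    n_edges: int = 600,
    coupling: float = 1.0,
    q_max: float = 0.95,
    q_min: float = 0.05,
    seed: int = 0,
    profile: str = "linear",
) -> PlantedOrderModel:
    """Build a planted-order model over N labeled nodes.

    The developmental order comes from a DPA growth run; ``q`` interpolates
    from ``q_max`` at rank 0 to ``q_min`` at the last rank (linearly by
    default, geometrically with ``profile="exponential"``), with the spread
    scaled by ``coupling`` around the midpoint.  ``coupling = 0`` yields the
    exchangeable null: every edge has probability ``(q_max + q_min) / 2``.
    """
    if n_edges > N * (N - 1) // 2:
        raise ValueError("n_edges exceeds the number of vertex pairs")
    if not 0 < q_min <= q_max <= 1:
        raise ValueError("need 0 < q_min <= q_max <= 1")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    order = _dpa_arrival_order(N, n_edges, rng)

    r = np.arange(n_edges)
    t = r / (n_edges - 1) if n_edges > 1 else np.zeros(1)
    if profile == "linear":
        base = q_max + (q_min - q_max) * t
    elif profile == "exponential":
        base = q_max * (q_min / q_max) ** t
    else:
        raise ValueError(f"unknown profile {profile!r}")
    mid = (q_max + q_min) / 2
    q = mid + coupling * (base - mid)

    width = len(str(N - 1))
    atlas = AtlasNodeSet(tuple(_node_label(i, width) for i in range(N)))
    edges = tuple(
        (_node_label(u, width), _node_label(v, width)) for u, v in order
    )
    return PlantedOrderModel(atlas, edges, q, coupling)


def sample_ensemble(
    model: PlantedOrderModel, n_subjects: int, seed: int = 0
) -> BrainGraphEnsemble:
    """Draw n independent subject graphs from the planted model.

    Each subject includes each ordered edge independently with its ``q``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    include = rng.random((n_subjects, model.n_edges)) < model.q
    width = len(str(n_subjects))
    graphs = []
    for s in range(n_subjects):
        edges = frozenset(
            model.ordered_edges[i] for i in np.flatnonzero(include[s])
        )
        graphs.append(SubjectGraph(f"s{s:0{width}d}", edges))
    return BrainGraphEnsemble(model.atlas, tuple(graphs))


def write_ensemble_dir(
    model: PlantedOrderModel,
    ensemble: BrainGraphEnsemble,
    out_dir: str | os.PathLike,
) -> None:
    """Write one GraphML per subject plus the ground-truth order TSV."""
    os.makedirs(out_dir, exist_ok=True)
    for g in ensemble.graphs:
        write_graphml(g, os.path.join(out_dir, f"{g.subject_id}.graphml"))
    truth = pd.DataFrame(
        {
            "rank": np.arange(model.n_edges),
            "u": [e[0] for e in model.ordered_edges],
            "v": [e[1] for e in model.ordered_edges],
            "q": model.q,
        }
    )
    truth.to_csv(os.path.join(out_dir, "ground_truth_order.tsv"), sep="\t", index=False)
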