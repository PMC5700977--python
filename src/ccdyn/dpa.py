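"""Doubly-preferential attachment (DPA) growth model for consensus dynamics.

The observed consensus connectome grows its edge count roughly exponentially
in the step index, and new edges overwhelmingly attach to the structure
already present.  The DPA model reproduces both features with four
parameters.  Starting from a small random seed graph on ``D`` of the ``N``
nodes, each synchronous step adds every currently absent edge ``uv``
independently with probability

    p_uv = B / (2(N-1)) * (deg u + deg v) + C,

where degrees are taken from the previous step.  The degree-proportional term
is "doubly" preferential — both endpoints contribute, unlike classic
preferential attachment where only the old endpoint's degree matters — and
summing it over all vertex pairs gives expected ``B * |E|`` new edges per
step, hence exponential growth at rate ``B``.  The constant ``C`` gives
zero-degree node pairs a small chance to spawn isolated edges, which the pure
degree rule forbids.

Fitting: ``A`` and ``B`` come from a log-linear regression of the observed
per-step edge counts (amplitude and rate of ``A * exp(B k)``).  Because the
``C`` term injects about ``binom(N,2) * C`` extra edges per step, which the
exponential growth then amplifies by the geometric series in ``1/(1+B)``, the
seed graph is shrunk from ``floor(A)`` to ``floor(A - binom(N,2) * C / B +
0.5)`` edges so the simulated curve still tracks ``A * exp(B k)``.  ``C``
itself is calibrated by ratio scaling against a target total of isolated
edges, exploiting that the total responds almost linearly to ``C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DPAParams",
    "SimulationState",
    "SimulationResult",
    "fit_exponential",
    "edge_probability",
    "adjusted_initial_edges",
    "initial_graph",
    "simulate_step",
    "expected_new_edges",
    "simulate",
    "calibrate_C",
]


@dataclass(frozen=True)
class DPAParams:
    """The four model parameters plus problem size, horizon and seed.

    N     node count (1015 for the standard anatomical parcellation)
    A     exponential amplitude from the edge-count regression
    B     exponential growth rate per step (also the degree-rule coefficient)
    C     per-pair inclusion probability allowing isolated edges
    D     number of nodes eligible for the random seed graph (a free
          parameter; the seed graph has far fewer edges than D(D-1)/2)
    steps growth steps to simulate (418 = one per subject of the reference
          ensemble, so step k aligns with the (n+1-k)-consensus connectome)
    """

    N: int = 1015
    A: float = 46.37
    B: float = 0.014
    C: float = 7.6e-7
    D: int = 60
    steps: int = 418
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.B < 1:
            raise ValueError("B must be in (0, 1)")
        if not 0 <= self.C < 1:
            raise ValueError("C must be in [0, 1)")
        if not 2 <= self.D <= self.N:
            raise ValueError("D must satisfy 2 <= D <= N")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@lru_cache(maxsize=8)
def _triu_pairs(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint arrays of all unordered vertex pairs, cached per N."""
    iu, iv = np.triu_indices(N, k=1)
    return iu.astype(np.int64), iv.astype(np.int64)


def _pair_index(i: np.ndarray, j: np.ndarray, N: int) -> np.ndarray:
    """Flat index of pair (i, j), i < j, in the row-major upper triangle."""
    return i * N - i * (i + 1) // 2 + (j - i - 1)


class SimulationState:
    """Mutable growth state: a simple graph over N integer-labeled nodes.

    Tracks the present-edge mask over all vertex pairs, per-node degrees, the
    step index, and per-step logs of new and new-isolated edge counts.
    """

    def __init__(self, N: int):
        self.N = N
        M = N * (N - 1) // 2
        self.present = np.zeros(M, dtype=bool)
        self.deg = np.zeros(N, dtype=np.int64)
        self.n_edges = 0
        self.step = 0
        self.edge_count_log: list[int] = []
        self.new_edge_log: list[int] = []
        self.new_isolated_log: list[int] = []

    def add_edges(self, u: np.ndarray, v: np.ndarray) -> None:
        """Insert edges (u[i], v[i]); pairs must be absent and u < v."""
        idx = _pair_index(u, v, self.N)
        if self.present[idx].any():
            raise ValueError("edge already present")
        self.present[idx] = True
        self.deg += np.bincount(u, minlength=self.N)
        self.deg += np.bincount(v, minlength=self.N)
        self.n_edges += len(idx)

    def edges(self) -> set[tuple[int, int]]:
        """Materialize the edge set (small-N introspection and tests)."""
        iu, iv = _triu_pairs(self.N)
        nz = np.flatnonzero(self.present)
        return {(int(iu[i]), int(iv[i])) for i in nz}

    @property
    def cumulative_isolated(self) -> int:
        return sum(self.new_isolated_log)


@dataclass(frozen=True)
class SimulationResult:
    """Averaged (and raw) per-step curves from repeated simulations."""

    params: DPAParams
    runs: int
    edge_counts: np.ndarray  # shape (runs, steps)
    new_isolated: np.ndarray  # shape (runs, steps)

    @property
    def steps(self) -> int:
        return self.params.steps

    @property
    def mean_edge_count(self) -> np.ndarray:
        return self.edge_counts.mean(axis=0)

    @property
    def cumulative_isolated(self) -> np.ndarray:
        """Per-run cumulative isolated-edge curves, shape (runs, steps)."""
        return self.new_isolated.cumsum(axis=1)

    @property
    def mean_cumulative_isolated(self) -> np.ndarray:
        return self.cumulative_isolated.mean(axis=0)

    @property
    def final_isolated_total(self) -> float:
        """Mean cumulative isolated-edge count at the final step."""
        return float(self.mean_cumulative_isolated[-1])

    def new_edges_mean(self) -> np.ndarray:
        # New edges at step 1 are counted against the seed graph, whose size
        # is identical across runs.
        m0 = adjusted_initial_edges(
            self.params.A, self.params.B, self.params.C, self.params.N
        )
        new = np.diff(self.edge_counts, axis=1, prepend=m0)
        return new.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        step = np.arange(1, self.steps + 1)
        return pd.DataFrame(
            {
                "step": step,
                "k": step,
                "edge_count": self.mean_edge_count,
                "new_edges": self.new_edges_mean(),
                "new_isolated": self.new_isolated.mean(axis=0),
                "cumulative_isolated": self.mean_cumulative_isolated,
            }
        )


def fit_exponential(
    edge_counts: Sequence[float], steps: Sequence[int] | None = None
) -> tuple[float, float, float]:
    """Fit ``count = A * exp(B * k)`` by least squares on the log scale.

    Returns ``(A, B, r_squared)`` where ``r_squared`` refers to the
    log-linear fit.  Steps default to ``1..len(edge_counts)``.
    """
    y = np.asarray(edge_counts, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("edge counts must be positive for a log-scale fit")
    k = np.arange(1, len(y) + 1) if steps is None else np.asarray(steps, dtype=float)
    res = stats.linregress(k, np.log(y))
    return float(math.exp(res.intercept)), float(res.slope), float(res.rvalue**2)


def edge_probability(deg_u, deg_v, params: DPAParams):
    """Per-step inclusion probability of an absent edge uv (clipped to [0,1]).

    Accepts scalars or arrays.  With ``C = 0`` this is the pure
    doubly-preferential rule, zero between two isolated nodes.
    """
    du = np.asarray(deg_u)
    dv = np.asarray(deg_v)
    if np.any(du < 0) or np.any(dv < 0):
        raise ValueError("degrees must be non-negative")
    p = params.B / (2 * (params.N - 1)) * (du + dv) + params.C
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def adjusted_initial_edges(A: float, B: float, C: float, N: int) -> int:
    """Seed-graph edge count compensating for the C term's extra edges.

    ``floor(A - binom(N,2) * C / B + 0.5)``, floored at zero.  With ``C = 0``
    this is simply ``floor(A)``.  The ``binom(N,2) * C`` is the expected
    number of C-edges per step over all vertex pairs; dividing by ``B`` sums
    the geometric series by which growth amplifies them.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    m = math.floor(A - math.comb(N, 2) * C / B + 0.5)
    return max(m, 0)


def initial_graph(
    m: int, D: int, N: int, seed: int | np.random.Generator = 0
) -> SimulationState:
    """Random seed graph: m distinct edges among D nodes chosen from N."""
    max_edges = D * (D - 1) // 2
    if m > max_edges:
        raise ValueError(f"m={m} exceeds D(D-1)/2={max_edges}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SimulationState(N)
    if m == 0:
        return state
    nodes = np.sort(rng.choice(N, size=D, replace=False))
    pi, pj = np.triu_indices(D, k=1)
    pick = rng.choice(len(pi), size=m, replace=False)
    state.add_edges(nodes[pi[pick]], nodes[pj[pick]])
    return state


def simulate_step(
    state: SimulationState, params: DPAParams, rng: np.random.Generator
) -> SimulationState:
    """Advance the growth process by one synchronous step (in place).

    Every currently absent pair uv is added independently with
    ``edge_probability`` computed from the *previous* step's degrees.  A new
    edge is logged as isolated when neither endpoint had positive degree
    before the step and it shares no endpoint with another edge added in the
    same step (i.e. it is isolated in the full post-step graph).
    """
    N = params.N
    iu, iv = _triu_pairs(N)
    deg_prev = state.deg
    p = params.B / (2 * (N - 1)) * (deg_prev[iu] + deg_prev[iv]) + params.C
    np.clip(p, 0.0, 1.0, out=p)
    p[state.present] = 0.0
    new = np.flatnonzero(rng.random(p.shape[0]) < p)
    u, v = iu[new], iv[new]

    if len(new):
        touch = np.bincount(u, minlength=N) + np.bincount(v, minlength=N)
        iso = (
            (deg_prev[u] == 0)
            & (deg_prev[v] == 0)
            & (touch[u] == 1)
            & (touch[v] == 1)
        )
        n_iso = int(iso.sum())
        state.present[new] = True
        state.deg = deg_prev + touch
        state.n_edges += len(new)
    else:
        n_iso = 0

    state.step += 1
    state.new_edge_log.append(len(new))
    state.new_isolated_log.append(n_iso)
    state.edge_count_log.append(state.n_edges)
    return state


def expected_new_edges(state: SimulationState, params: DPAParams) -> float:
    """Expected new-edge count ``B * |E|`` of the pure degree rule (C = 0).

    The closed form ignores already-present pairs, matching the analytic
    derivation: summing ``B/(2(N-1)) * (deg u + deg v)`` over *all* vertex
    pairs telescopes to ``B * |E|``.  The exhaustive pair sum is evaluated as
    a consistency cross-check and must agree to machine precision.
    """
    iu, iv = _triu_pairs(state.N)
    coeff = params.B / (2 * (params.N - 1))
    exhaustive = float(coeff * (state.deg[iu] + state.deg[iv]).sum())
    analytic = params.B * state.n_edges
    if not math.isclose(exhaustive, analytic, rel_tol=1e-9, abs_tol=1e-12):
        raise AssertionError(
            f"pair-sum {exhaustive} disagrees with B|E| = {analytic}"
        )
    return analytic


def simulate(params: DPAParams, runs: int = 10) -> SimulationResult:
    """Run the model ``runs`` times and collect per-step curves.

    Each run starts from a fresh seed graph with
    ``adjusted_initial_edges(A, B, C, N)`` edges on ``D`` random nodes and
    advances ``params.steps`` synchronous steps.  Per-run RNG streams are
    spawned deterministically from ``params.seed``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    m0 = adjusted_initial_edges(params.A, params.B, params.C, params.N)
    if m0 > params.D * (params.D - 1) // 2:
        raise ValueError(
            f"initial edge count {m0} exceeds capacity of D={params.D} nodes"
        )
    streams = np.random.SeedSequence(params.seed).spawn(runs)
    edge_counts = np.empty((runs, params.steps), dtype=np.int64)
    new_isolated = np.empty((runs, params.steps), dtype=np.int64)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        state = initial_graph(m0, params.D, params.N, rng)
        for _ in range(params.steps):
            simulate_step(state, params, rng)
        edge_counts[r] = state.edge_count_log
        new_isolated[r] = state.new_isolated_log
    return SimulationResult(params, runs, edge_counts, new_isolated)


def calibrate_C(
    params: DPAParams,
    target_isolated_total: float,
    runs: int = 10,
    seed: int | None = None,
    rel_tol: float = 0.05,
    max_iter: int = 5,
) -> float:
    """Calibrate C by ratio scaling against a target isolated-edge total.

    The cumulative number of isolated edges responds almost linearly to C
    (two isolated edges rarely collide on a node in one step), so dividing
    the provisional C by the ratio of the simulated total to the target
    lands near the right value; the step is iterated until the simulated
    total is within ``rel_tol`` of the target or ``max_iter`` is reached.
    """
    if params.C <= 0:
        raise ValueError("provisional C must be positive")
    if target_isolated_total <= 0:
        raise ValueError("target must be positive")
    C = params.C
    base_seed = params.seed if seed is None else seed
    for it in range(max_iter):
        trial = DPAParams(
            N=params.N, A=params.A, B=params.B, C=C, D=params.D,
            steps=params.steps, seed=base_seed + it,
        )
        total = simulate(trial, runs=runs).final_isolated_total
        if total == 0:
            if it == max_iter - 1:
                raise RuntimeError(
                    "simulation produced no isolated edges with C > 0"
                )
            C *= 2.0
            continue
        ratio = total / target_isolated_total
        if abs(ratio - 1.0) <= rel_tol:
            return C
        C = C / ratio
    return C
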