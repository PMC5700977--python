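"""Quarter-set robustness of the consensus dynamics.

If the order in which edges enter the growing consensus sequence reflects a
biological property rather than sampling noise, it should barely depend on
which subjects are used to build it.  The check: partition the subject
ensemble into ``g`` disjoint, size-balanced groups (the default ``g = 4``
gives "quarter sets"), build the consensus appearance order separately per
group, and estimate the probability that two randomly chosen items (edges or
vertices, among those present in every group) appear in strictly opposite
order in two randomly chosen groups.  Under a random-order null this
*discordance probability* is 1/2; the smaller it is, the more robust the
dynamics.

A cross-ensemble mode compares the quarter sets of two independently built
ensembles (e.g. the same subjects processed with deterministic versus
probabilistic tractography), drawing one group from each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .consensus import AppearanceOrder, EdgeFrequencyTable

__all__ = [
    "QuarterPartition",
    "DiscordanceEstimate",
    "quarter_partition",
    "common_items",
    "discordance",
    "cross_ensemble_discordance",
]


@dataclass(frozen=True)
class QuarterPartition:
    """A balanced random partition of subject indices into ``g`` groups."""

    group_of: tuple[int, ...]  # subject index -> group id in 0..g-1
    g: int
    seed: int

    def __post_init__(self) -> None:
        sizes = self.sizes()
        if max(sizes) - min(sizes) > 1:
            raise ValueError("group sizes must differ by at most 1")
        if sorted(set(self.group_of)) != list(range(self.g)):
            raise ValueError("groups must cover 0..g-1")

    def sizes(self) -> list[int]:
        counts = [0] * self.g
        for gid in self.group_of:
            counts[gid] += 1
        return counts

    def groups(self) -> list[list[int]]:
        """Subject indices per group, in subject order."""
        out: list[list[int]] = [[] for _ in range(self.g)]
        for i, gid in enumerate(self.group_of):
            out[gid].append(i)
        return out


@dataclass(frozen=True)
class DiscordanceEstimate:
    """Estimated probability that two items appear in opposite order."""

    probability: float
    n_samples: int
    standard_error: float
    item_kind: str  # "edge" | "vertex"
    mode: str  # "within-ensemble" | "cross-ensemble"
    n_common_items: int


def quarter_partition(n_subjects: int, g: int = 4, seed: int = 0) -> QuarterPartition:
    """Uniformly random partition into ``g`` groups of near-equal size.

    Group sizes differ by at most one (418 subjects into 4 groups gives
    sizes 105, 105, 104, 104).  Deterministic given the seed.
    """
    if g < 2:
        raise ValueError("need at least 2 groups")
    if g > n_subjects:
        raise ValueError(f"cannot split {n_subjects} subjects into {g} groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    group_of = [0] * n_subjects
    for pos, subject in enumerate(perm):
        group_of[subject] = pos % g
    return QuarterPartition(tuple(group_of), g, seed)


def common_items(
    tables: Sequence[EdgeFrequencyTable], kind: str = "edge"
) -> set:
    """Items present in every table.

    Edges: pairs stored (frequency >= 1) in all tables.  Vertices: nodes with
    at least one stored incident edge in all tables.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    atlas = tables[0].atlas
    if any(t.atlas.labels != atlas.labels for t in tables[1:]):
        raise ValueError("tables must share one atlas")
    if kind == "edge":
        sets = [set(t.freq) for t in tables]
    elif kind == "vertex":
        sets = [t.stored_vertices() for t in tables]
    else:
        raise ValueError(f"unknown item kind {kind!r}")
    return set.intersection(*sets)


def _step_matrix(orders: Sequence[AppearanceOrder], items: Sequence) -> np.ndarray:
    """Rows: groups; columns: items; entries: appearance steps."""
    mat = np.empty((len(orders), len(items)), dtype=np.int64)
    for gi, order in enumerate(orders):
        for ii, item in enumerate(items):
            s = order.step_of(item)
            if s is None:
                raise ValueError(
                    f"item {item!r} never appears in group {gi}; restrict to "
                    "common items first"
                )
            mat[gi, ii] = s
    return mat


def _discordant_mask(
    sx_e: np.ndarray, sx_f: np.ndarray, sy_e: np.ndarray, sy_f: np.ndarray
) -> np.ndarray:
    # Order reversal in either direction; ties are concordant (the event
    # requires "strictly before" on both sides).
    return ((sx_e < sx_f) & (sy_f < sy_e)) | ((sx_f < sx_e) & (sy_e < sy_f))


def _estimate(
    steps_x: np.ndarray,
    steps_y: np.ndarray,
    distinct_groups_within: bool,
    n_samples: int,
    seed: int,
    exhaustive: bool,
    item_kind: str,
    mode: str,
) -> DiscordanceEstimate:
    gx, n_items = steps_x.shape
    gy = steps_y.shape[0]
    if n_items < 2:
        raise ValueError("need at least 2 common items")

    if exhaustive:
        hits = 0
        total = 0
        if distinct_groups_within:
            group_pairs = list(combinations(range(gx), 2))
        else:
            group_pairs = [(a, b) for a in range(gx) for b in range(gy)]
        item_pairs = np.array(list(combinations(range(n_items), 2)))
        e_idx, f_idx = item_pairs[:, 0], item_pairs[:, 1]
        for a, b in group_pairs:
            mask = _discordant_mask(
                steps_x[a, e_idx], steps_x[a, f_idx],
                steps_y[b, e_idx], steps_y[b, f_idx],
            )
            hits += int(mask.sum())
            total += mask.size
        p = hits / total
        se = math.sqrt(p * (1 - p) / total)
        return DiscordanceEstimate(p, total, se, item_kind, mode, n_items)

    rng = np.random.default_rng(seed)
    if distinct_groups_within:
        a = rng.integers(0, gx, size=n_samples)
        b = rng.integers(0, gx - 1, size=n_samples)
        b = np.where(b >= a, b + 1, b)  # uniform over groups != a
    else:
        a = rng.integers(0, gx, size=n_samples)
        b = rng.integers(0, gy, size=n_samples)
    e = rng.integers(0, n_items, size=n_samples)
    f = rng.integers(0, n_items - 1, size=n_samples)
    f = np.where(f >= e, f + 1, f)  # uniform over items != e
    mask = _discordant_mask(
        steps_x[a, e], steps_x[a, f], steps_y[b, e], steps_y[b, f]
    )
    p = float(mask.mean())
    se = math.sqrt(p * (1 - p) / n_samples)
    return DiscordanceEstimate(p, n_samples, se, item_kind, mode, n_items)


def discordance(
    orders: Sequence[AppearanceOrder],
    items: Sequence,
    n_samples: int = 1_000_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> DiscordanceEstimate:
    """Probability that two items appear in opposite order in two groups.

    Samples (with replacement) a uniformly random pair of *distinct* groups
    (X, Y) and a uniformly random pair of distinct items {e, f}, and counts
    the event that e appears strictly before f in X while f appears strictly
    before e in Y, or vice versa.  Ties in appearance step are concordant.
    ``exhaustive=True`` enumerates every group pair and item pair instead of
    sampling (feasible for small item sets).
    """
    if len(orders) < 2:
        raise ValueError("need at least 2 group orders")
    items = sorted(items)
    kind = orders[0].kind
    steps = _step_matrix(orders, items)
    return _estimate(
        steps, steps, True, n_samples, seed, exhaustive, kind, "within-ensemble"
    )


def cross_ensemble_discordance(
    orders_a: Sequence[AppearanceOrder],
    orders_b: Sequence[AppearanceOrder],
    items: Sequence,
    n_samples: int = 1_000_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> DiscordanceEstimate:
    """Discordance with group X drawn from ensemble A and Y from ensemble B.

    ``items`` must be present in every group order of both ensembles (the
    cross-common set).
    """
    if not orders_a or not orders_b:
        raise ValueError("both ensembles need at least one group order")
    items = sorted(items)
    if len(items) < 2:
        raise ValueError("need at least 2 cross-common items")
    kind = orders_a[0].kind
    steps_a = _step_matrix(orders_a, items)
    steps_b = _step_matrix(orders_b, items)
    return _estimate(
        steps_a, steps_b, False, n_samples, seed, exhaustive, kind, "cross-ensemble"
    )
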