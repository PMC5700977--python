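"""Reading and writing braingraph ensembles and trajectory tables.

A *braingraph* (structural connectome) is an undirected simple graph whose
nodes are anatomically labeled gray-matter regions (ROIs) and whose edges mark
axonal fiber connections discovered between them.  Ensembles of such graphs —
one per subject, all over a shared atlas of node labels — are the input to all
consensus-connectome computations.

Supported on-disk formats:

* GraphML (one undirected graph per file, as distributed for public
  HCP-derived braingraph collections),
* plain edge-list TSV (two tab-separated label columns, ``#`` comments,
  no header),
* trajectory TSV (``step``, ``k``, ``edge_count``, ``new_edges``,
  ``new_isolated``, ``cumulative_isolated``).

Node identity is by string label, never positional index, so ensembles from
different sources align by atlas label.  Edge weights and other attributes are
ignored: consensus dynamics uses binary edge presence only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "AtlasNodeSet",
    "SubjectGraph",
    "BrainGraphEnsemble",
    "canonical_edge",
    "read_graphml",
    "read_edgelist",
    "read_subject_graph",
    "read_ensemble",
    "write_graphml",
    "write_trajectory",
    "read_trajectory",
    "TRAJECTORY_COLUMNS",
]

#: Column order of the trajectory TSV dialect.
TRAJECTORY_COLUMNS = (
    "step",
    "k",
    "edge_count",
    "new_edges",
    "new_isolated",
    "cumulative_isolated",
)


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered node pair ``{u, v}`` in canonical (sorted) form."""
    if u == v:
        raise ValueError(f"self-loop {u!r}-{v!r} is not a valid edge")
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class AtlasNodeSet:
    """An ordered set of unique node labels shared by all subject graphs."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("atlas needs at least 2 labels")

    @property
    def N(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in set(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "AtlasNodeSet":
        return cls(tuple(labels))


@dataclass(frozen=True)
class SubjectGraph:
    """One subject's braingraph: an undirected simple edge set over labels."""

    subject_id: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} in subject {self.subject_id!r}")
            if u > v:
                raise ValueError("edges must be canonical (sorted) pairs")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return {x for e in self.edges for x in e}

    @classmethod
    def from_pairs(
        cls, subject_id: str, pairs: Iterable[tuple[str, str]]
    ) -> "SubjectGraph":
        """Build from raw pairs, dropping self-loops and duplicate edges."""
        edges = frozenset(
            canonical_edge(u, v) for u, v in pairs if u != v
        )
        return cls(subject_id, edges)


@dataclass(frozen=True)
class BrainGraphEnsemble:
    """``n`` subject graphs over one shared atlas."""

    atlas: AtlasNodeSet
    graphs: tuple[SubjectGraph, ...]

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError("ensemble needs at least one subject graph")
        atlas_set = set(self.atlas.labels)
        for g in self.graphs:
            stray = g.nodes() - atlas_set
            if stray:
                raise ValueError(
                    f"subject {g.subject_id!r} uses labels outside the atlas: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def n(self) -> int:
        return len(self.graphs)

    @classmethod
    def from_graphs(
        cls,
        graphs: Sequence[SubjectGraph],
        atlas: AtlasNodeSet | None = None,
    ) -> "BrainGraphEnsemble":
        """Assemble an ensemble; the atlas defaults to the union of labels."""
        if atlas is None:
            labels = sorted({x for g in graphs for x in g.nodes()})
            atlas = AtlasNodeSet(tuple(labels))
        return cls(atlas, tuple(graphs))


def _label_of(node: object, data: dict, label_attr: str | None) -> str:
    if label_attr is not None and label_attr in data:
        return str(data[label_attr])
    return str(node)


def read_graphml(
    path: str | os.PathLike,
    *,
    subject_id: str | None = None,
    label_attr: str | None = "name",
    symmetrize: bool = False,
) -> SubjectGraph:
    """Read one subject graph from a GraphML file.

    Self-loops are dropped and parallel edges collapsed.  Node labels come
    from the ``label_attr`` node attribute when present (default ``"name"``),
    falling back to the GraphML node id.  A directed-graph declaration is
    rejected unless ``symmetrize=True``, in which case each arc is read as an
    undirected edge.
    """
    g = nx.read_graphml(path)
    if g.is_directed():
        if not symmetrize:
            raise ValueError(
                f"{path}: GraphML declares a directed graph; pass "
                "symmetrize=True to read arcs as undirected edges"
            )
        g = g.to_undirected()
    labels = {node: _label_of(node, data, label_attr) for node, data in g.nodes(data=True)}
    pairs = ((labels[u], labels[v]) for u, v in g.edges())
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SubjectGraph.from_pairs(subject_id, pairs)


def read_edgelist(
    path: str | os.PathLike, *, subject_id: str | None = None
) -> SubjectGraph:
    """Read a subject graph from a two-column tab-separated edge list.

    Lines starting with ``#`` and blank lines are skipped; no header is
    expected.  Extra columns beyond the first two are ignored.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated labels")
            pairs.append((parts[0], parts[1]))
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SubjectGraph.from_pairs(subject_id, pairs)


def read_subject_graph(path: str | os.PathLike, **kwargs) -> SubjectGraph:
    """Read a subject graph, dispatching on file extension.

    ``.graphml``/``.xml`` go through :func:`read_graphml`; everything else is
    treated as edge-list TSV.
    """
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".graphml", ".xml"):
        return read_graphml(path, **kwargs)
    return read_edgelist(path, **kwargs)


def read_ensemble(
    paths: Sequence[str | os.PathLike],
    atlas: AtlasNodeSet | None = None,
    **kwargs,
) -> BrainGraphEnsemble:
    """Read an ensemble from a list of per-subject graph files.

    Subject order equals path order.  If no atlas is given, the union of node
    labels across all files becomes the atlas; if one is given, any label
    outside it is an error.
    """
    if not paths:
        raise ValueError("read_ensemble needs at least one path")
    graphs = [read_subject_graph(p, **kwargs) for p in paths]
    return BrainGraphEnsemble.from_graphs(graphs, atlas)


def write_graphml(graph: SubjectGraph, path: str | os.PathLike) -> None:
    """Write one subject graph as undirected GraphML."""
    g = nx.Graph()
    g.add_edges_from(graph.edges)
    nx.write_graphml(g, path)


def write_trajectory(traj, path: str | os.PathLike) -> None:
    """Write a trajectory (consensus dynamics or simulation) as TSV.

    ``traj`` is anything with a ``to_frame()`` returning the standard
    trajectory columns, or a DataFrame already in that layout.
    """
    frame = traj if isinstance(traj, pd.DataFrame) else traj.to_frame()
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory frame lacks columns {missing}")
    frame.loc[:, list(TRAJECTORY_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | os.PathLike) -> pd.DataFrame:
    """Read a trajectory TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")
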