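"""Polyhedral graphs underlying coiled-coil protein origami (CCPO) cages.

A CCPO cage realises a polyhedron in which every edge is a coiled-coil
dimer.  The abstract shape is therefore just a simple connected graph;
this module provides a validated wrapper around :class:`networkx.Graph`
plus the small catalogue of polyhedra used in CCPO design work
(tetrahedron, square pyramid, trigonal prism/bipyramid, octahedron).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx

__all__ = ["PolyhedralGraph", "build_polyhedron", "BUILTIN_POLYHEDRA"]

Edge = tuple[Hashable, Hashable]

#: Edge listings of the built-in polyhedra.  Vertex labels are integers;
#: for bipyramids/pyramids the apex vertices carry the highest labels.
BUILTIN_POLYHEDRA: dict[str, list[Edge]] = {
    "tetrahedron": [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
    "trigonal_bipyramid": [
        (0, 1), (1, 2), (0, 2),                       # equatorial triangle
        (3, 0), (3, 1), (3, 2),                       # upper apex
        (4, 0), (4, 1), (4, 2),                       # lower apex
    ],
    "square_pyramid": [
        (0, 1), (1, 2), (2, 3), (3, 0),
        (4, 0), (4, 1), (4, 2), (4, 3),
    ],
    "trigonal_prism": [
        (0, 1), (1, 2), (0, 2),
        (3, 4), (4, 5), (3, 5),
        (0, 3), (1, 4), (2, 5),
    ],
    "octahedron": [
        (0, 1), (1, 2), (2, 3), (3, 0),
        (4, 0), (4, 1), (4, 2), (4, 3),
        (5, 0), (5, 1), (5, 2), (5, 3),
    ],
}


class GraphValidationError(ValueError):
    """Raised when an edge listing does not describe a valid cage graph."""


@dataclass(frozen=True)
class PolyhedralGraph:
    """A simple, connected graph whose edges are CC-dimer slots.

    Parameters
    ----------
    edges
        Unordered vertex pairs.  Duplicate edges (in either order) and
        self-loops are rejected; the graph must be connected.
    name
        Free-text label, e.g. ``"trigonal_bipyramid"``.
    """

    edges: tuple[Edge, ...]
    name: str = "graph"
    _graph: nx.Graph = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        seen: set[frozenset] = set()
        g = nx.Graph()
        for u, v in self.edges:
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphValidationError(f"duplicate edge {u!r}-{v!r}")
            seen.add(key)
            g.add_edge(u, v)
        if g.number_of_edges() < 1:
            raise GraphValidationError("graph must have at least one edge")
        if not nx.is_connected(g):
            raise GraphValidationError("graph is not connected")
        object.__setattr__(self, "_graph", g)

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def vertices(self) -> tuple[Hashable, ...]:
        return tuple(sorted(self._graph.nodes))

    @property
    def n_vertices(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def neighbors(self, v: Hashable) -> list[Hashable]:
        return sorted(self._graph.neighbors(v))

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "vertices": list(self.vertices),
                "edges": [list(e) for e in self.edges],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PolyhedralGraph":
        obj = json.loads(text)
        return cls(edges=tuple(tuple(e) for e in obj["edges"]),
                   name=obj.get("name", "graph"))


def build_polyhedron(spec: str | Iterable[Sequence[Hashable]],
                     name: str | None = None) -> PolyhedralGraph:
    """Build a validated cage graph from a built-in name or an edge list.

    >>> build_polyhedron("trigonal_bipyramid").n_edges
    9
    """
    if isinstance(spec, str):
        try:
            edges = BUILTIN_POLYHEDRA[spec]
        except KeyError:
            raise GraphValidationError(
                f"unknown polyhedron {spec!r}; built-ins: "
                f"{sorted(BUILTIN_POLYHEDRA)}"
            ) from None
        return PolyhedralGraph(edges=tuple(edges), name=name or spec)
    edges = tuple(tuple(e) for e in spec)
    return PolyhedralGraph(edges=edges, name=name or "custom")
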