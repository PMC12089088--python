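"""Exact integer arithmetic on the honeycomb (graphene) lattice.

Every lattice point is stored as an integer pair ``(i, j)`` standing for the
Cartesian point ``(i*sqrt(3)/2, j/2)`` with bond length 1.  In this frame a
pointy-topped hexagonal cell centred at a lattice point has its six corners at
the offsets in :data:`CORNERS`, nearest-neighbour bonds are exactly the six
offsets in :data:`EDGE_OFFSETS`, and adjacent cell centres differ by one of
:data:`CELL_NEIGHBORS`.  Working in this basis keeps every construction and
every atom-merging step purely combinatorial -- two atoms coincide iff their
integer coordinates are equal.
"""

from __future__ import annotations

import math

IJ = tuple[int, int]

#: Corner offsets of a hexagonal cell, counter-clockwise starting at 30 deg.
CORNERS: list[IJ] = [(1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1)]

#: Centre offsets of the six adjacent cells, counter-clockwise from 0 deg.
CELL_NEIGHBORS: list[IJ] = [(2, 0), (1, 3), (-1, 3), (-2, 0), (-1, -3), (1, -3)]

#: The six bond vectors of the honeycomb lattice (length 1).
EDGE_OFFSETS: list[IJ] = [(1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1)]

#: Bond vector -> direction label d in 0..5 (bearing 30 + 60 d degrees).
DIRECTION_OF_OFFSET: dict[IJ, int] = {
    (1, 1): 0, (0, 2): 1, (-1, 1): 2, (-1, -1): 3, (0, -2): 4, (1, -1): 5,
}

_SQRT3_2 = math.sqrt(3.0) / 2.0


def cartesian(p: IJ) -> tuple[float, float]:
    """Cartesian coordinates (bond-length units) of a lattice point."""
    return (p[0] * _SQRT3_2, p[1] / 2.0)


def cell_corners(center: IJ) -> list[IJ]:
    """The six corner points of the hexagonal cell at *center* (CCW)."""
    return [(center[0] + dx, center[1] + dy) for dx, dy in CORNERS]


def induced_graph(cells: list[IJ]) -> tuple[set[IJ], set[tuple[IJ, IJ]]]:
    """Vertices and edges of the benzenoid spanned by the given cells.

    The vertex set is the union of all cell corners; the edge set is every
    honeycomb bond between two included vertices (the induced subgraph of the
    infinite lattice).  Edges are stored once, as lexicographically sorted
    pairs.
    """
    vertices: set[IJ] = set()
    for c in cells:
        vertices.update(cell_corners(c))
    edges: set[tuple[IJ, IJ]] = set()
    for v in vertices:
        for dx, dy in EDGE_OFFSETS:
            w = (v[0] + dx, v[1] + dy)
            if w in vertices:
                edges.add((v, w) if v < w else (w, v))
    return vertices, edges
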