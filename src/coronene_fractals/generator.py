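"""Construction of the three coronene-fractal families.

A fractal is obtained by placing one coronene unit (the C24 skeleton of seven
peri-fused hexagons) at every vertex of a small benzenoid *template* and
fusing the units of adjacent template vertices along one shared rim bond.
Three template families are implemented:

``ZHCF(n)``
    zigzag hexagonal: the hexagon-shaped benzenoid of cell radius n-1
    (benzene, coronene, circumcoronene, ...), 6n^2 template vertices.
``AHCF(n)``
    armchair hexagonal: cells whose cube coordinates satisfy
    max(|a-b|, |b-c|, |c-a|) <= 3(n-1) (benzene, hexabenzocoronene, ...).
``RCF(m, n)``
    rectangular: n vertex-disjoint rows of m linearly fused hexagons, stacked
    with perylene-type junction bonds (one per cell column).

Vertex substitution multiplies the template counts as |V| = 24 V_T - 2 E_T
and |E| = 30 V_T - E_T, which reproduces the closed-form polynomials
|V(ZHCF(n))| = 126n^2 + 6n, |E(ZHCF(n))| = 171n^2 + 3n, and the analogous
AHCF/RCF forms, together with the degree-based edge partition
{(2,2): 6V_T - 2E_T, (2,3): 12V_T - 4E_T, (3,3): 12V_T + 5E_T}.
``generate`` refuses to return a graph that violates any of these counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import hexlattice as hexl
from .graph import EdgePartition, MolecularGraph
from .hexlattice import IJ

FAMILIES = ("ZHCF", "AHCF", "RCF")


@dataclass(frozen=True)
class FractalSpec:
    """Family and size parameters of a coronene fractal.

    ``n`` is the template size parameter; ``m`` (hexagons per row) applies to
    the rectangular family only.
    """

    family: str
    n: int
    m: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if self.family == "RCF":
            if self.m is None or self.m < 1:
                raise ValueError("RCF requires a positive m (hexagons per row)")
        elif self.m is not None:
            raise ValueError(f"{self.family} takes no m parameter")

    @property
    def label(self) -> str:
        if self.family == "RCF":
            return f"RCF({self.m},{self.n})"
        return f"{self.family}({self.n})"


@dataclass(frozen=True)
class CoroneneUnit:
    """The labelled C24 coronene skeleton used as the substitution unit.

    Atom labels 0..5 are the inner hexagon ``i0..i5`` (counter-clockwise,
    ``i0`` at bearing -30 deg); labels 6..23 are the rim 18-cycle ``r0..r17``
    with ``r0`` the spoke partner of ``i0``.  For each direction
    ``d in 0..5`` the fusable bond ``F_d = (r_{3d+1}, r_{3d+2})`` is the
    outermost (2,2) rim bond facing bearing 60 d degrees; fusing two adjacent
    units identifies the endpoints of one such bond pairwise.
    """

    offsets: tuple[IJ, ...]          # label -> lattice offset from the unit centre
    bonds: tuple[tuple[int, int], ...]
    fusable: dict[int, tuple[int, int]]  # direction d -> (label, label)

    @property
    def inner(self) -> tuple[int, ...]:
        return tuple(range(6))

    @property
    def rim(self) -> tuple[int, ...]:
        return tuple(range(6, 24))

    def graph(self) -> MolecularGraph:
        coords = {i: hexl.cartesian(p) for i, p in enumerate(self.offsets)}
        return MolecularGraph.from_bonds(
            self.bonds, coords=coords, family_tag="coronene unit",
            atoms=range(24),
        )


@dataclass(frozen=True)
class Template:
    """A direction-labelled benzenoid template on the honeycomb lattice.

    Edges are stored as ``(u, v, d)`` with ``u < v`` lexicographically and
    ``d`` the direction label seen from ``u`` (the other endpoint sees
    ``(d + 3) mod 6``).
    """

    vertices: tuple[IJ, ...]
    edges: tuple[tuple[IJ, IJ, int], ...]

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        used: set[tuple[IJ, int]] = set()
        for u, v, d in self.edges:
            off = (v[0] - u[0], v[1] - u[1])
            if off not in hexl.DIRECTION_OF_OFFSET or hexl.DIRECTION_OF_OFFSET[off] != d:
                raise ValueError(f"edge {u}-{v} is not a direction-{d} lattice bond")
            if u not in vset or v not in vset:
                raise ValueError(f"edge {u}-{v} references missing vertex")
            for key in ((u, d), (v, (d + 3) % 6)):
                if key in used:
                    raise ValueError(f"direction clash at template vertex {key[0]}")
                used.add(key)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Coronene unit
# ---------------------------------------------------------------------------


def _bearing(p: IJ) -> float:
    x, y = hexl.cartesian(p)
    return math.atan2(y, x)


def coronene_unit() -> CoroneneUnit:
    """Build the labelled coronene unit (24 atoms, 30 bonds)."""
    cells = [(0, 0)] + hexl.CELL_NEIGHBORS
    vertices, edges = hexl.induced_graph(cells)
    inner = hexl.cell_corners((0, 0))
    rim = [v for v in vertices if v not in set(inner)]

    # inner hexagon CCW starting at bearing -30 deg (exact lattice order)
    inner_sorted = [(1, -1), (1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2)]
    assert set(inner_sorted) == set(inner)

    # walk the rim 18-cycle CCW from the spoke partner of i0
    adj: dict[IJ, list[IJ]] = {v: [] for v in rim}
    rim_set = set(rim)
    for a, b in edges:
        if a in rim_set and b in rim_set:
            adj[a].append(b)
            adj[b].append(a)
    start: IJ = (2, -2)  # radial neighbour of i0 = (1, -1)
    first = max(adj[start], key=_bearing)  # CCW successor
    cycle = [start, first]
    while len(cycle) < 18:
        nxt = [w for w in adj[cycle[-1]] if w != cycle[-2]]
        cycle.append(nxt[0])

    order = inner_sorted + cycle
    label_of = {p: i for i, p in enumerate(order)}
    bonds = tuple(sorted(tuple(sorted((label_of[a], label_of[b]))) for a, b in edges))
    fusable = {d: (6 + 3 * d + 1, 6 + 3 * d + 2) for d in range(6)}
    unit = CoroneneUnit(tuple(order), bonds, fusable)

    # sanity: F_d must be the (2,2) bond whose endpoints line up with the
    # fusable bond of a unit fused in direction d
    for d, (la, lb) in unit.fusable.items():
        dx, dy = hexl.CELL_NEIGHBORS[d]
        d2 = (d + 3) % 6
        la2, lb2 = unit.fusable[d2]
        pa, pb = unit.offsets[la], unit.offsets[lb]
        qa = (unit.offsets[lb2][0] + 3 * dx, unit.offsets[lb2][1] + 3 * dy)
        qb = (unit.offsets[la2][0] + 3 * dx, unit.offsets[la2][1] + 3 * dy)
        assert (pa, pb) == (qa, qb), "fusable-bond labelling out of register"
    return unit


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _cell_center(q: int, s: int) -> IJ:
    """Centre of the cell with axial coordinates (q, s)."""
    return (2 * q + s, 3 * s)


def _zhcf_cells(n: int) -> list[IJ]:
    r = n - 1
    return [
        _cell_center(q, s)
        for q in range(-r, r + 1)
        for s in range(-r, r + 1)
        if abs(q + s) <= r
    ]


def _ahcf_cells(n: int) -> list[IJ]:
    # cube coordinates (a, b, c) = (q, -q-s, s); pairwise differences
    r = 3 * (n - 1)
    out = []
    for q in range(-r, r + 1):
        for s in range(-r, r + 1):
            if max(abs(2 * q + s), abs(q + 2 * s), abs(q - s)) <= r:
                out.append(_cell_center(q, s))
    return out


def _rcf_cells(m: int, n: int) -> list[IJ]:
    # n rows of m linearly fused cells; a j-offset of -6 per row leaves the
    # rows vertex-disjoint and creates exactly one vertical junction bond per
    # cell column between consecutive rows (perylene-type stacking)
    return [(2 * k, -6 * r) for r in range(n) for k in range(m)]


def build_template(spec: FractalSpec) -> Template:
    """Construct the direction-labelled benzenoid template for *spec*."""
    if spec.family == "ZHCF":
        cells = _zhcf_cells(spec.n)
    elif spec.family == "AHCF":
        cells = _ahcf_cells(spec.n)
    else:
        cells = _rcf_cells(spec.m, spec.n)
    vertices, edges = hexl.induced_graph(cells)
    labelled = tuple(
        sorted(
            (u, v, hexl.DIRECTION_OF_OFFSET[(v[0] - u[0], v[1] - u[1])])
            for u, v in edges
        )
    )
    return Template(tuple(sorted(vertices)), labelled)


def template_counts(spec: FractalSpec) -> tuple[int, int]:
    """Closed-form (V_T, E_T) of the template for *spec*."""
    n = spec.n
    if spec.family == "ZHCF":
        return 6 * n * n, 9 * n * n - 3 * n
    if spec.family == "AHCF":
        return 18 * n * n - 18 * n + 6, 27 * n * n - 33 * n + 12
    m = spec.m
    return n * (4 * m + 2), 6 * m * n - m + n


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


class FusionError(RuntimeError):
    """Inconsistent fusion request during template expansion."""


def _unit_center(t: IJ) -> IJ:
    """Unit centre for a template vertex.

    The template frame is rotated by -30 degrees and scaled by 3*sqrt(3) so
    that adjacent template vertices map to unit centres exactly one fused
    coronene-coronene spacing apart; both factors are exact in the integer
    lattice basis.
    """
    i, j = t
    return (3 * (3 * i + j) // 2, 9 * (j - i) // 2)


def expand_template(t: Template, orientation: str = "standard") -> MolecularGraph:
    """Expand a template into a molecular graph of fused coronene units.

    One coronene unit is created per template vertex; for each template edge
    with direction ``d`` the fusable bonds ``F_d`` (of the smaller endpoint)
    and ``F_{(d+3) mod 6}`` (of the larger) are identified endpoint-for-
    endpoint with a union-find, i.e. the fused bond is stored once.  With the
    default orientation the merged atoms also coincide geometrically, which
    is asserted; ``orientation="swapped"`` exchanges the two identifications
    (producing an isomorphic graph without coherent coordinates).
    """
    if orientation not in ("standard", "swapped"):
        raise ValueError("orientation must be 'standard' or 'swapped'")
    unit = coronene_unit()
    parent: dict[tuple[IJ, int], tuple[IJ, int]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for v in t.vertices:
        for lbl in range(24):
            parent[(v, lbl)] = (v, lbl)

    used: set[tuple[IJ, int]] = set()
    for u, v, d in t.edges:
        d2 = (d + 3) % 6
        for key in ((u, d), (v, d2)):
            if key in used:
                raise FusionError(f"fusable bond F_{key[1]} of unit {key[0]} used twice")
            used.add(key)
        fa, fb = unit.fusable[d]
        ga, gb = unit.fusable[d2]
        if orientation == "standard":
            union((u, fa), (v, gb))
            union((u, fb), (v, ga))
        else:
            union((u, fa), (v, ga))
            union((u, fb), (v, gb))

    def position(node: tuple[IJ, int]) -> IJ:
        (tv, lbl) = node
        cx, cy = _unit_center(tv)
        ox, oy = unit.offsets[lbl]
        return (cx + ox, cy + oy)

    # collect equivalence classes
    classes: dict[tuple[IJ, int], list[tuple[IJ, int]]] = {}
    for node in parent:
        classes.setdefault(find(node), []).append(node)

    if orientation == "standard":
        pos_of_root: dict[tuple[IJ, int], IJ] = {}
        for root, members in classes.items():
            positions = {position(nd) for nd in members}
            if len(positions) != 1:
                raise FusionError("fused atoms do not coincide geometrically")
            pos_of_root[root] = positions.pop()
        if len(set(pos_of_root.values())) != len(pos_of_root):
            raise FusionError("distinct atoms collapse to one lattice point")
        roots = sorted(pos_of_root, key=lambda r: pos_of_root[r])
        atom_id = {r: i for i, r in enumerate(roots)}
        coords = {atom_id[r]: hexl.cartesian(pos_of_root[r]) for r in roots}
    else:
        roots = sorted(classes, key=lambda r: min(classes[r]))
        atom_id = {r: i for i, r in enumerate(roots)}
        coords = None

    bonds: set[tuple[int, int]] = set()
    for tv in t.vertices:
        for la, lb in unit.bonds:
            a = atom_id[find((tv, la))]
            b = atom_id[find((tv, lb))]
            bonds.add((a, b) if a < b else (b, a))
    return MolecularGraph.from_bonds(
        sorted(bonds), coords=coords, atoms=range(len(roots))
    )


# ---------------------------------------------------------------------------
# Closed forms and validated generation
# ---------------------------------------------------------------------------


def closed_form_counts(spec: FractalSpec) -> tuple[int, int, EdgePartition]:
    """Exact (|V|, |E|, edge partition) from the closed-form polynomials."""
    n = spec.n
    if spec.family == "ZHCF":
        part = {
            (2, 2): 18 * n * n + 6 * n,
            (2, 3): 36 * n * n + 12 * n,
            (3, 3): 117 * n * n - 15 * n,
        }
        nv = 126 * n * n + 6 * n
    elif spec.family == "AHCF":
        part = {
            (2, 2): 54 * n * n - 42 * n + 12,
            (2, 3): 108 * n * n - 84 * n + 24,
            (3, 3): 351 * n * n - 381 * n + 132,
        }
        nv = 378 * n * n - 366 * n + 120
    else:
        m = spec.m
        part = {
            (2, 2): 12 * m * n + 2 * m + 10 * n,
            (2, 3): 24 * m * n + 4 * m + 20 * n,
            (3, 3): 78 * m * n - 5 * m + 29 * n,
        }
        nv = 84 * m * n + 2 * m + 46 * n
    return nv, sum(part.values()), part


def generate(spec: FractalSpec) -> MolecularGraph:
    """Generate and validate the coronene fractal for *spec*.

    The expanded graph is checked against the closed-form vertex, edge and
    partition counts; any mismatch raises instead of returning a
    non-conforming structure.
    """
    template = build_template(spec)
    g = expand_template(template)
    nv, ne, part = closed_form_counts(spec)
    if g.n_atoms != nv:
        raise FusionError(f"{spec.label}: got {g.n_atoms} atoms, expected {nv}")
    if g.n_bonds != ne:
        raise FusionError(f"{spec.label}: got {g.n_bonds} bonds, expected {ne}")
    actual = g.edge_partition()
    if actual != part:
        raise FusionError(
            f"{spec.label}: edge partition {actual} != closed form {part}"
        )
    return MolecularGraph(g.atoms, g.bonds, g.coords, family_tag=spec.label)


def benzenoid_from_cells(cells: list[IJ], family_tag: str | None = None) -> MolecularGraph:
    """Molecular graph of an arbitrary benzenoid given its hexagon cells.

    Convenience constructor for small polycyclic fixtures (naphthalene,
    pyrene, ...); cells are centre points in lattice coordinates.
    """
    vertices, edges = hexl.induced_graph(cells)
    order = sorted(vertices)
    idx = {p: i for i, p in enumerate(order)}
    coords = {i: hexl.cartesian(p) for p, i in idx.items()}
    return MolecularGraph.from_bonds(
        [(idx[a], idx[b]) for a, b in edges],
        coords=coords,
        family_tag=family_tag,
        atoms=range(len(order)),
    )
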