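"""Molecular-graph container, degree machinery and plain-text I/O.

The carbon skeleton of a benzenoid or coronoid system is modelled as a simple
undirected graph.  Atoms are opaque dense integers; bonds are unordered pairs.
Optional 2D coordinates (bond-length units) accompany generator output so that
structures can be exported to XYZ/SDF and so that a canonical, reproducible
atom ordering exists for matrix export.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

Bond = tuple[int, int]
#: Mapping from a sorted endpoint-degree pair (d(a), d(b)) to the number of
#: bonds |Ei| in that class.
EdgePartition = dict[tuple[int, int], int]


class ParseError(ValueError):
    """Malformed edge-list input."""


@dataclass(frozen=True)
class MolecularGraph:
    """An all-carbon molecular graph.

    Parameters
    ----------
    atoms
        Atom identifiers (dense integers, assigned in generation order).
    bonds
        Unordered atom pairs, stored as sorted tuples without duplicates.
    coords
        Optional mapping atom -> (x, y) in bond-length units.
    family_tag
        Optional provenance label, e.g. ``"ZHCF(2)"``.
    """

    atoms: tuple[int, ...]
    bonds: tuple[Bond, ...]
    coords: dict[int, tuple[float, float]] | None = None
    family_tag: str | None = None

    def __post_init__(self) -> None:
        atom_set = set(self.atoms)
        if len(atom_set) != len(self.atoms):
            raise ValueError("duplicate atom ids")
        seen: set[Bond] = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-loop on atom {a}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if a not in atom_set or b not in atom_set:
                raise ValueError(f"bond {key} references unknown atom")

    @classmethod
    def from_bonds(
        cls,
        bonds,
        coords=None,
        family_tag=None,
        atoms=None,
    ) -> "MolecularGraph":
        """Build a graph from an iterable of bonds, inferring the atom set."""
        norm = tuple(tuple(sorted(b)) for b in bonds)
        if atoms is None:
            atoms = tuple(sorted({a for b in norm for a in b}))
        return cls(tuple(atoms), norm, coords, family_tag)

    # -- basic invariants ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degrees(self) -> dict[int, int]:
        deg = dict.fromkeys(self.atoms, 0)
        for a, b in self.bonds:
            deg[a] += 1
            deg[b] += 1
        return deg

    def max_degree(self) -> int:
        """Delta(G), the maximum vertex degree."""
        if not self.atoms:
            raise ValueError("empty graph has no maximum degree")
        return max(self.degrees().values())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.atoms)
        g.add_edges_from(self.bonds)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def is_bipartite(self) -> bool:
        return nx.is_bipartite(self.to_networkx())

    # -- degree-based edge partition ---------------------------------------

    def edge_partition(self) -> EdgePartition:
        """Partition bonds by the sorted degree pair of their endpoints."""
        if not self.atoms:
            raise ValueError("cannot partition an empty graph")
        deg = self.degrees()
        counts = Counter(
            tuple(sorted((deg[a], deg[b]))) for a, b in self.bonds
        )
        return dict(sorted(counts.items()))

    # -- matrix export ------------------------------------------------------

    def atom_order(self) -> list[int]:
        """Canonical atom ordering used for all matrix exports.

        Atoms are sorted lexicographically by coordinates when present
        (making spectra bit-for-bit reproducible across runs), otherwise by
        atom id.
        """
        if self.coords is not None:
            return sorted(self.atoms, key=lambda a: self.coords[a])
        return sorted(self.atoms)

    def adjacency_matrix(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix in canonical atom order."""
        order = self.atom_order()
        pos = {a: i for i, a in enumerate(order)}
        n = len(order)
        mat = np.zeros((n, n), dtype=np.int64)
        for a, b in self.bonds:
            mat[pos[a], pos[b]] = 1
            mat[pos[b], pos[a]] = 1
        return mat


# ---------------------------------------------------------------------------
# Plain-text formats
# ---------------------------------------------------------------------------


def read_edge_list(path) -> MolecularGraph:
    """Read a graph from a plain edge list (one bond per line, 1-based ids).

    Lines starting with ``#`` and blank lines are ignored.  Atom ids in the
    file are arbitrary positive integers; internally they are relabelled to
    dense 0-based integers in sorted order.
    """
    bonds: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}, line {lineno}: expected two atom ids, got {line!r}"
                )
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-integer atom id in {line!r}"
                ) from None
            if a < 1 or b < 1:
                raise ParseError(
                    f"{path}, line {lineno}: atom ids must be positive (1-based)"
                )
            if a == b:
                raise ParseError(f"{path}, line {lineno}: self-loop on atom {a}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise ParseError(f"{path}, line {lineno}: duplicate bond {key}")
            seen.add(key)
            bonds.append(key)
    if not bonds:
        raise ParseError(f"{path}: no bonds found")
    ids = sorted({a for bond in bonds for a in bond})
    relabel = {old: new for new, old in enumerate(ids)}
    return MolecularGraph.from_bonds(
        [(relabel[a], relabel[b]) for a, b in bonds]
    )


def write_edge_list(g: MolecularGraph, path) -> None:
    """Write a 1-based edge list in canonical atom order."""
    order = {a: i + 1 for i, a in enumerate(g.atom_order())}
    lines = sorted(
        tuple(sorted((order[a], order[b]))) for a, b in g.bonds
    )
    with open(path, "w") as fh:
        if g.family_tag:
            fh.write(f"# {g.family_tag}\n")
        for a, b in lines:
            fh.write(f"{a} {b}\n")


def write_xyz(g: MolecularGraph, path, bond_length: float = 1.42) -> None:
    """Write an XYZ file (all atoms carbon, z = 0).

    ``bond_length`` rescales the unit-bond-length coordinates to Angstroms;
    the default 1.42 is the aromatic C-C distance.
    """
    if g.coords is None:
        raise ValueError("graph has no coordinates; cannot write XYZ")
    order = g.atom_order()
    with open(path, "w") as fh:
        fh.write(f"{g.n_atoms}\n")
        fh.write(f"{g.family_tag or 'molecular graph'}\n")
        for a in order:
            x, y = g.coords[a]
            fh.write(f"C {x * bond_length:.6f} {y * bond_length:.6f} 0.000000\n")


def write_sdf(g: MolecularGraph, path, bond_length: float = 1.42) -> None:
    """Write a minimal MOL/SDF V2000 record (all C, all single bonds)."""
    if g.coords is None:
        raise ValueError("graph has no coordinates; cannot write SDF")
    order = g.atom_order()
    pos = {a: i + 1 for i, a in enumerate(order)}
    lines = [g.family_tag or "molecular graph", "  corofrac", ""]
    lines.append(
        f"{g.n_atoms:>3d}{g.n_bonds:>3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in order:
        x, y = g.coords[a]
        lines.append(
            f"{x * bond_length:>10.4f}{y * bond_length:>10.4f}{0.0:>10.4f}"
            " C   0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for a, b in sorted((min(pos[a], pos[b]), max(pos[a], pos[b])) for a, b in g.bonds):
        lines.append(f"{a:>3d}{b:>3d}  1  0  0  0  0")
    lines.append("M  END")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")
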