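"""Modified reverse degree and the twelve degree-based topological indices.

The modified reverse degree of a vertex of degree ``d`` in a graph with
maximum degree ``Delta`` is

    MkR(d) = Delta - d + k            if k <= d,
             (Delta - d + k) mod Delta  otherwise,

with a tunable integer parameter ``k >= 1``.  A topological index is then the
sum over bonds of a fixed symmetric function of the two endpoint reverse
degrees; because the fractal families have only three degree classes, the sum
collapses to three terms weighted by the edge-partition counts.

The catalog covers the first/second Zagreb, forgotten, Sombor,
geometric-arithmetic, hyper-Zagreb, harmonic, first/second redefined Zagreb,
bi-Zagreb, tri-Zagreb and geometric bi-Zagreb indices.
"""

from __future__ import annotations

import math
from typing import Callable

import sympy

from .generator import FractalSpec, closed_form_counts
from .graph import EdgePartition, MolecularGraph

#: Edge-contribution formulas TI(x, y) on a pair of modified reverse degrees.
#: Each takes an optional ``sqrt`` so the same formula serves double-precision
#: evaluation (math.sqrt) and exact radical arithmetic (sympy.sqrt).
CATALOG: dict[str, Callable] = {
    "M1": lambda x, y, sqrt=math.sqrt: x + y,
    "M2": lambda x, y, sqrt=math.sqrt: x * y,
    "F": lambda x, y, sqrt=math.sqrt: x * x + y * y,
    "S": lambda x, y, sqrt=math.sqrt: sqrt(x * x + y * y),
    "GA": lambda x, y, sqrt=math.sqrt: 2 * sqrt(x * y) / (x + y),
    "HZ": lambda x, y, sqrt=math.sqrt: (x + y) ** 2,
    "H": lambda x, y, sqrt=math.sqrt: 2 / (x + y),
    "ReZ1": lambda x, y, sqrt=math.sqrt: (x + y) / (x * y),
    "ReZ2": lambda x, y, sqrt=math.sqrt: (x * y) / (x + y),
    "BM": lambda x, y, sqrt=math.sqrt: x + y + x * y,
    "TM": lambda x, y, sqrt=math.sqrt: x * x + y * y + x * y,
    "GBM": lambda x, y, sqrt=math.sqrt: sqrt(x * y) / (x + y + x * y),
}

INDEX_NAMES = tuple(CATALOG)

#: Indices whose contributions are integers for integer reverse degrees.
INTEGER_INDICES = frozenset({"M1", "M2", "F", "HZ", "BM", "TM"})


class ZeroReverseDegreeError(ValueError):
    """A modified reverse degree of zero reached an index evaluation."""


def modified_reverse_degree(d: int, k: int, delta: int) -> int:
    """Modified reverse degree MkR(d) for maximum degree *delta*.

    The result may be zero through the mod branch for some (d, k, delta);
    index evaluation rejects such values explicitly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 1 <= d <= delta:
        raise ValueError(f"degree {d} outside 1..{delta}")
    if k <= d:
        return delta - d + k
    return (delta - d + k) % delta


def edge_contribution(index: str, x, y):
    """TI(x, y) for the named index; symmetric in its arguments."""
    if index not in CATALOG:
        raise KeyError(f"unknown index {index!r}; known: {', '.join(CATALOG)}")
    if x < 1 or y < 1:
        raise ZeroReverseDegreeError(
            f"index {index} undefined for reverse degrees ({x}, {y})"
        )
    return CATALOG[index](x, y)


def _reverse_partition(
    partition: EdgePartition, k: int, delta: int
) -> list[tuple[int, int, int]]:
    """Map a degree partition to (count, MkR(da), MkR(db)) triples."""
    out = []
    for (da, db), count in sorted(partition.items()):
        xa = modified_reverse_degree(da, k, delta)
        xb = modified_reverse_degree(db, k, delta)
        for d, x in ((da, xa), (db, xb)):
            if x == 0:
                raise ZeroReverseDegreeError(
                    f"MkR(d)=0 for degree {d} with k={k}, Delta={delta}"
                )
        out.append((count, xa, xb))
    return out


def index_value_from_partition(
    partition: EdgePartition, index: str, k: int, delta: int
) -> float:
    """Index value as a partition-weighted sum of edge contributions."""
    if index not in CATALOG:
        raise KeyError(f"unknown index {index!r}")
    return sum(
        count * CATALOG[index](xa, xb)
        for count, xa, xb in _reverse_partition(partition, k, delta)
    )


def index_value(g: MolecularGraph, index: str, k: int) -> float:
    """Index value of a molecular graph; Delta is taken from the graph."""
    return index_value_from_partition(g.edge_partition(), index, k, g.max_degree())


def index_value_closed_form(spec: FractalSpec, index: str, k: int) -> float:
    """Index value of a fractal family member via the closed-form partition.

    Exact integer arithmetic for the integer-valued indices, double precision
    otherwise.  All fractals have Delta = 3, so k in {1, 2, 3} avoids the mod
    branch; larger k is accepted and handled through it.
    """
    _, _, partition = closed_form_counts(spec)
    return index_value_from_partition(partition, index, k, delta=3)


def partition_polynomials(family: str) -> dict[tuple[int, int], "sympy.Expr"]:
    """Edge-partition counts of a family as sympy polynomials in n (and m)."""
    n, m = sympy.symbols("n m", positive=True, integer=True)
    if family == "ZHCF":
        return {
            (2, 2): 18 * n**2 + 6 * n,
            (2, 3): 36 * n**2 + 12 * n,
            (3, 3): 117 * n**2 - 15 * n,
        }
    if family == "AHCF":
        return {
            (2, 2): 54 * n**2 - 42 * n + 12,
            (2, 3): 108 * n**2 - 84 * n + 24,
            (3, 3): 351 * n**2 - 381 * n + 132,
        }
    if family == "RCF":
        return {
            (2, 2): 12 * m * n + 2 * m + 10 * n,
            (2, 3): 24 * m * n + 4 * m + 20 * n,
            (3, 3): 78 * m * n - 5 * m + 29 * n,
        }
    raise ValueError(f"unknown family {family!r}")


def index_polynomial(family: str, index: str, k: int):
    """Closed-form index polynomial in the size parameters, as a sympy expression.

    Returns an exact polynomial in ``n`` (and ``m`` for RCF) whose radical or
    rational coefficients evaluate to the decimal coefficients of the printed
    family tables.
    """
    if index not in CATALOG:
        raise KeyError(f"unknown index {index!r}")
    partition = partition_polynomials(family)
    total = sympy.Integer(0)
    for (da, db), count in partition.items():
        xa = sympy.Integer(modified_reverse_degree(da, k, 3))
        xb = sympy.Integer(modified_reverse_degree(db, k, 3))
        if xa == 0 or xb == 0:
            raise ZeroReverseDegreeError(f"MkR=0 in class ({da},{db}) for k={k}")
        total += count * CATALOG[index](xa, xb, sqrt=sympy.sqrt)
    return sympy.expand(total)
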