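"""Hückel adjacency-spectrum energetics.

Within simple Hückel theory the pi-system of an all-carbon conjugated
molecule is characterised by the eigenvalues of the 0/1 adjacency matrix
(energies ``alpha + lambda_i * beta``; all results here are in dimensionless
beta units).  From the sorted spectrum this module derives the total
pi-electron energy, HOMO-LUMO gap, spectral diameter, per-atom energy and
delocalization energy, and from the exact determinant the Kekulé structure
count and Herndon resonance energy.  The coronene fractals are bipartite, so
the Coulson-Rushbrooke pairing theorem applies: the spectrum is symmetric
about zero and |det A| is the square of the number of perfect matchings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .graph import MolecularGraph


@dataclass(frozen=True)
class SpectralReport:
    """All spectrum-derived energetic descriptors of one structure."""

    eigenvalues: tuple[float, ...]   # ascending, beta units
    e_pi: float                      # total pi-electron energy
    homo: float                      # lambda_H
    lumo: float                      # lambda_L
    gap: float                       # lambda_H - lambda_L
    spectral_diameter: float         # lambda_max - lambda_min
    e_pi_per_atom: float
    deloc_per_atom: float            # (E_pi - p) / p
    kekule_count: int | None         # exact; None when not computed
    resonance_per_atom: float | None  # 1.185 ln(KC) / p


def spectrum(g: MolecularGraph) -> np.ndarray:
    """Adjacency eigenvalues in ascending order (symmetric solver)."""
    if g.n_atoms == 0:
        raise ValueError("empty graph has no spectrum")
    return np.linalg.eigvalsh(g.adjacency_matrix().astype(float))


def total_pi_energy(eigenvalues, p: int | None = None) -> float:
    """Total pi-electron energy from the sorted spectrum.

    Even atom count: twice the sum of the p/2 largest eigenvalues (each
    bonding orbital doubly occupied).  Odd: the middle eigenvalue is singly
    occupied.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    if p is None:
        p = len(ev)
    if p != len(ev):
        raise ValueError("spectrum length does not match atom count")
    if p % 2 == 0:
        return float(2.0 * ev[p // 2:].sum())
    half = (p - 1) // 2
    return float(ev[half] + 2.0 * ev[half + 1:].sum())


def homo_lumo_gap(eigenvalues, p: int | None = None) -> tuple[float, float, float]:
    """(HOMO, LUMO, gap) selected by rank in the sorted spectrum.

    The p/2 largest eigenvalues are the occupied levels; the HOMO is the
    smallest of them and the LUMO the largest unoccupied one, so the gap is
    the difference of the two middle eigenvalues.  Rank selection avoids
    sign-threshold failures near zero eigenvalues.  For bipartite graphs the
    gap equals 2*lambda_H by pairing symmetry.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    if p is None:
        p = len(ev)
    if p != len(ev):
        raise ValueError("spectrum length does not match atom count")
    if p < 2:
        raise ValueError("need at least two eigenvalues")
    if p % 2:
        warnings.warn(
            "odd atom count: gap taken between the levels flanking the "
            "singly occupied median orbital",
            stacklevel=2,
        )
        half = (p + 1) // 2
    else:
        half = p // 2
    homo, lumo = float(ev[half]), float(ev[half - 1])
    return homo, lumo, homo - lumo


def spectral_diameter(eigenvalues) -> float:
    """lambda_max - lambda_min of the spectrum."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty spectrum")
    return float(ev.max() - ev.min())


def per_atom_energies(e_pi: float, p: int) -> tuple[float, float]:
    """(E_pi / p, (E_pi - p) / p): energy and delocalization energy per atom."""
    if p <= 0:
        raise ValueError("atom count must be positive")
    return e_pi / p, (e_pi - p) / p


# ---------------------------------------------------------------------------
# Exact determinant, Kekulé count, resonance energy
# ---------------------------------------------------------------------------


def exact_determinant(matrix) -> int:
    """Determinant of an integer matrix by fraction-free Bareiss elimination.

    All arithmetic is in Python big integers; every division in the Bareiss
    recurrence is exact.  |det A| exceeds 2^53 already for the 132-atom
    fractals, so floating point is not an option here.
    """
    m = [[int(x) for x in row] for row in np.asarray(matrix)]
    n = len(m)
    if any(len(row) != n for row in m):
        raise ValueError("matrix must be square")
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for col in range(n - 1):
        if m[col][col] == 0:
            for r in range(col + 1, n):
                if m[r][col] != 0:
                    m[col], m[r] = m[r], m[col]
                    sign = -sign
                    break
            else:
                return 0
        pivot = m[col][col]
        for i in range(col + 1, n):
            row_i, row_c = m[i], m[col]
            factor = row_i[col]
            for j in range(col + 1, n):
                row_i[j] = (pivot * row_i[j] - factor * row_c[j]) // prev
            row_i[col] = 0
        prev = pivot
    return sign * m[-1][-1]


def kekule_count(g: MolecularGraph) -> int:
    """Number of Kekulé structures as sqrt|det A|, exactly.

    For bipartite graphs with an even atom count the absolute constant term
    of the characteristic polynomial, |det A|, equals the squared number of
    perfect matchings of benzenoid-type systems.  The square-root check is a
    diagnostic: a non-perfect-square determinant means the relation does not
    hold for the given graph and an error is raised rather than a wrong
    count returned.
    """
    if g.n_atoms % 2:
        raise ValueError("Kekulé structures require an even atom count")
    if not g.is_bipartite():
        raise ValueError("Kekulé count via determinant requires a bipartite graph")
    det = abs(exact_determinant(g.adjacency_matrix()))
    root = math.isqrt(det)
    if root * root != det:
        raise ValueError(
            f"|det A| = {det} is not a perfect square; "
            "determinant-based Kekulé counting is inapplicable to this graph"
        )
    return root


def resonance_per_atom(kc: int, p: int) -> float:
    """Herndon resonance energy per atom: 1.185 ln(KC) / p (beta units)."""
    if kc < 1:
        raise ValueError("resonance energy undefined without Kekulé structures")
    if p <= 0:
        raise ValueError("atom count must be positive")
    return 1.185 * math.log(kc) / p


def count_perfect_matchings(g: MolecularGraph) -> int:
    """Brute-force perfect-matching count by recursive enumeration.

    Exponential; intended as an independent oracle for graphs of up to a few
    dozen atoms.
    """
    adjacency = {a: set() for a in g.atoms}
    for a, b in g.bonds:
        adjacency[a].add(b)
        adjacency[b].add(a)
    if len(g.atoms) % 2:
        return 0

    def recurse(unmatched: frozenset) -> int:
        if not unmatched:
            return 1
        a = min(unmatched)
        total = 0
        for b in adjacency[a] & unmatched:
            total += recurse(unmatched - {a, b})
        return total

    return recurse(frozenset(g.atoms))


def spectral_report(g: MolecularGraph, kekule: bool | None = None) -> SpectralReport:
    """Full energetic characterisation of one structure.

    ``kekule=None`` (auto) computes the exact Kekulé count only for graphs
    of at most 200 atoms; the exact determinant is cubic in big-integer
    arithmetic and grows expensive far beyond that.
    """
    ev = spectrum(g)
    p = g.n_atoms
    e_pi = total_pi_energy(ev, p)
    homo, lumo, gap = homo_lumo_gap(ev, p)
    e_per_atom, deloc = per_atom_energies(e_pi, p)
    if kekule is None:
        kekule = p <= 200
    kc = re = None
    if kekule:
        kc = kekule_count(g)
        re = resonance_per_atom(kc, p) if kc >= 1 else None
    return SpectralReport(
        eigenvalues=tuple(float(x) for x in ev),
        e_pi=e_pi,
        homo=homo,
        lumo=lumo,
        gap=gap,
        spectral_diameter=spectral_diameter(ev),
        e_pi_per_atom=e_per_atom,
        deloc_per_atom=deloc,
        kekule_count=kc,
        resonance_per_atom=re,
    )
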