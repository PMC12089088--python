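# coronene-fractals

Graph-theoretic characterisation of two-dimensional coronene fractals:
structure generation, modified reverse degree-based topological indices,
index-weighted graph entropy with relative complexity measures, Hückel
spectral energetics, and linear structure–property (QSPR) models.

Coronene fractals are benzenoid/coronoid carbon lattices built by repeating
the C24 coronene motif (seven peri-fused hexagons) over a template: a
zigzag hexagonal series ZHCF(n), an armchair hexagonal series AHCF(n), and
a rectangular series RCF(m, n). They are models for graphene nanoflakes and
macrocyclic ("kekulene-like") carbon architectures studied for organic
semiconductors and molecular electronics. The package is aimed at
cheminformatics and materials researchers who need reproducible descriptors
and stability proxies for such lattices without electronic-structure
calculations.

## What it computes

**Structures.** `generate(FractalSpec(family, n[, m]))` builds the explicit
molecular graph (atoms, bonds, planar coordinates) by vertex-substitution of
a coronene unit on a benzenoid template, fusing adjacent units along one
shared rim bond. Every output is validated against the closed-form counts,
e.g. |V(ZHCF(n))| = 126n² + 6n, |E(ZHCF(n))| = 171n² + 3n, and the
degree-class edge partition {E₂₂, E₂₃, E₃₃}.

**Indices.** The modified reverse degree with parameter k ≥ 1 is

    MkR(d) = Δ(G) − d + k           if k ≤ d
             (Δ(G) − d + k) mod Δ   otherwise

and a topological index is TI(G) = Σ_{ab∈E} TI(MkR(d(a)), MkR(d(b))) for any
of twelve edge-contribution functions (first/second Zagreb, forgotten,
Sombor, geometric–arithmetic, hyper-Zagreb, harmonic, redefined Zagrebs,
bi-/tri-Zagreb, geometric bi-Zagreb). Exact closed forms in n (and m) are
available per family.

**Entropy.** Each bond gets probability f(ab)/TI(G); the graph entropy in
bits is I = log₂TI − (1/TI)·Σ f·log₂f, with structural information content
SIC = I/log₂TI and bond information content BIC = I/log₂|E| as
size-corrected complexity measures.

**Spectra.** From the adjacency eigenvalues (β units): total π-electron
energy Eπ = 2·Σ occupied λᵢ, HOMO–LUMO gap ΔG = λ_H − λ_L, spectral diameter
SD = λ_max − λ_min, delocalization energy per atom (Eπ − |V|)/|V|, exact
Kekulé count KC = √|det A| by big-integer elimination, and Herndon resonance
energy RE = 1.185·ln(KC)/|V|.

**QSPR.** Ordinary least squares P = R·x + c over the eleven tabulated
reference structures, with the k=2 first Zagreb index (for Eπ) or its
entropy (for the other five properties) as descriptor, reporting r²,
adjusted r², SE and F.

## Worked example

```python
from coronene_fractals import (FractalSpec, generate, graph_entropy,
                               spectral_report)

g = generate(FractalSpec("ZHCF", 2))
print(g.n_atoms, g.n_bonds)          # 516 690

rep = graph_entropy(g, "M1", k=1)
print(round(rep.ti_value), round(rep.entropy_bits, 8))
# 1716 9.37722247  -> the first Zagreb index and its entropy in bits

small = generate(FractalSpec("ZHCF", 1))
sp = spectral_report(small)
print(round(sp.e_pi, 3), round(sp.gap, 4), sp.kekule_count)
# 194.662 0.7638 37718065  -> pi-energy (beta), HOMO-LUMO gap, Kekulé count
```

The 1716 is the k=1 first-Zagreb total over the 690 bonds; 9.377 bits is
the Shannon entropy of the bond-contribution distribution (upper bound
log₂690 ≈ 9.43, so the lattice is nearly uniform); 194.662 β and 0.7638 β
are the Hückel total energy and gap of the 132-atom size-1 member, and
37,718,065 is its exact number of Kekulé resonance structures.

The `examples/` directory has one short narrative script per capability,
and the `corofrac` command exposes the same operations from a shell
(`corofrac generate ZHCF 2 --xyz z.xyz`, `corofrac report --out out/`).

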