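# Methods

## Structural model

All three fractal families are modelled as simple, connected, bipartite,
planar graphs with maximum degree 3 — the carbon skeletons of benzenoid or
coronoid π-systems, hydrogens omitted. The construction is
vertex-substitution: a small benzenoid *template* on the honeycomb lattice
is chosen per family, a 24-atom coronene unit is placed at each template
vertex, and units on adjacent template vertices are fused by identifying the
two endpoints of one outer rim bond (the "fusable" (2,2) bond facing the
neighbour). Substitution multiplies counts as

    |V| = 24·V_T − 2·E_T        |E| = 30·V_T − E_T
    E₂₂ = 6·V_T − 2·E_T         E₂₃ = 12·V_T − 4·E_T        E₃₃ = 12·V_T + 5·E_T

and these identities, applied to the template-count polynomials, reproduce
the published closed forms of all three families exactly (verified
symbolically in the test suite). The templates are:

- **ZHCF(n)** — hexagon-shaped benzenoid of cell radius n−1 (benzene,
  coronene, circumcoronene, …): V_T = 6n², E_T = 9n² − 3n.
- **AHCF(n)** — cells whose cube coordinates satisfy
  max(|a−b|, |b−c|, |c−a|) ≤ 3(n−1) (benzene, hexabenzocoronene, …):
  V_T = 18n² − 18n + 6, E_T = 27n² − 33n + 12.
- **RCF(m, n)** — n vertex-disjoint rows of m linearly fused hexagons,
  stacked with one perylene-type junction bond per cell column:
  V_T = n(4m+2), E_T = 6mn − m + n.

The template size n is a lattice size parameter, not a recursion depth: no
multi-generation self-similar recursion is applied, because the closed-form
counts grow quadratically, which a true recursive substitution would not.
All three families coincide at size 1 (a macrocyclic, kekulene-like ring of
six coronene units with a central hole), which the generated spectra
confirm.

### Exact lattice arithmetic

Every construction step runs on integer coordinates: lattice point (i, j)
stands for the Cartesian point (i·√3/2, j/2) at bond length 1. Hexagon
corners, bond vectors and cell adjacency are fixed integer offsets, so atom
identity is integer equality and the unit-merging step is purely
combinatorial — no floating-point coincidence detection anywhere. The
template frame is rotated −30° and scaled by 3√3 relative to the unit frame
(both exact in this basis), which makes fused rim atoms of adjacent units
land on identical lattice points; the expansion asserts that coincidence.
Atom ordering for all matrix exports is lexicographic in the integer
coordinates, so adjacency matrices and spectra are bit-for-bit reproducible.

### Fusion orientation

Identifying the endpoint pairs of two fused rim bonds can be done two ways.
The geometric (standard) orientation is pinned in `generate`; the swapped
alternative is exposed in `expand_template` for scrutiny. On acyclic
(tree) templates the two give isomorphic graphs — the mirror image of one
subtree realises the swap. On cyclic templates they genuinely differ: the
all-swapped gluing of the 6-cycle size-1 template yields a connected,
bipartite, count-identical but non-isomorphic "twisted" isomer. This is why
orientation is part of the structural definition and not a free choice; the
tests assert both behaviours.

## Indices and entropy

The modified reverse degree MkR(d) = Δ−d+k (for k ≤ d, else mod Δ) can hit
zero through the mod branch; since several contribution functions are then
singular or zero, any zero reverse degree raises instead of propagating
infinities — it cannot occur for the fractal families with k ≤ 3. The
geometric bi-Zagreb contribution is √(xy)/(x+y+xy); the other eleven are the
standard textbook forms. Index totals use exact integer arithmetic where
the contributions are integers (M1, M2, F, HZ, BM, TM) and double precision
otherwise; symbolic closed forms (sympy, exact radicals) are available per
family and are derived from the edge-partition polynomials rather than
transcribed from printed decimal tables, which carry their own intermediate
rounding (observed at the ~10⁻³ absolute level on coefficients of order
500).

Graph entropy is computed in bits via the simplified two-term form
I = log₂TI − (1/TI)·Σ f·log₂f, aggregated over the three degree classes
(exact to machine precision); the defining per-edge −Σ p·log₂p path is also
implemented and cross-checked to 10⁻¹². I ≤ log₂|E| always (Jensen), with
equality exactly for uniform contributions. SIC = I/log₂TI is only
guaranteed ≤ 1 when every contribution is ≥ 1 (true for all Zagreb-type
indices used in the complexity analysis); for indices with fractional
contributions (GA, GBM, harmonic at some k) SIC can slightly exceed 1, and
the package reports the computed value without clamping.

## Spectral energetics

Eigenvalues come from a dense symmetric solver in double precision; all
energetic quantities are in dimensionless β units. HOMO and LUMO are
selected by rank (the two middle eigenvalues for even atom counts), never
by sign threshold, which is robust near zero eigenvalues; for bipartite
inputs the gap equals 2λ_H by Coulson–Rushbrooke pairing, which the suite
verifies to 10⁻⁹. For odd atom counts (radicals, outside the families) the
gap is taken between the levels flanking the singly occupied median orbital
and a warning is issued. "Per bond" columns of the published table are
divisions by the atom count |V| (verified numerically, e.g.
194.662/132 = 1.4747); the API names them `per_atom`.

The Kekulé count is √|det A| with the determinant computed by fraction-free
Bareiss elimination in Python big integers (|det A| ≈ 1.4·10¹⁵ already at
132 atoms, and intermediate minors far exceed 2⁵³, ruling out floating
point). For any bipartite graph |det A| = det(B)² is automatically a
perfect square; the square-root check is kept as a defensive diagnostic.
The real applicability condition is benzenoid-type sign coherence
(Dewar–Longuet-Higgins): on non-benzenoid bipartite graphs √|det A| counts
matchings *with signs* and can undercount (cube graph: 3 vs 9), which a
test documents. Whether the relation is exact for the hole-containing
size-1 coronoid members is not independently established here; the computed
count (37,718,065 for the 132-atom member) reproduces the published
resonance energy to 10⁻⁵ per atom, which is consistent with sign coherence.
The Bareiss determinant is cubic with growing big-integer entries — fast to
~500 atoms, expensive beyond ~1000 — so `spectral_report` computes Kekulé
counts automatically only up to 200 atoms, and the resonance-energy column
is computed on demand elsewhere.

## QSPR models

Fits are univariate OLS (statsmodels) with r² the squared Pearson
correlation, adj r² = 1 − (1−r²)(n−1)/(n−2), SE = √(RSS/(n−2)) and
F = r²(n−2)/(1−r²); the internal consistency of F with r² is asserted. The
fitting set is the eleven structures with tabulated spectral properties —
ZHCF(1–4), AHCF(1–3), RCF(1–4) under the square convention m = n — which is
recorded in the dataset object; the tables do not state the set explicitly,
and this reconstruction reproduces every published coefficient at its
printed precision. The total-energy model uses the raw M2RM1 index as
descriptor; the other five use its entropy, as published. The published
r² = 0.999 for the energy model is a truncation: the published F statistic
pins r² at ≈ 0.9999995, and the refit agrees with that F to ~10⁻⁵ relative.
Property values for fitting can be the published ones (`mode="paper"`) or
recomputed (`mode="computed"`); recomputed spectral values agree with the
published ones to better than 10⁻² per value. Recomputing the
resonance-energy column requires exact determinants of up to 2040×2040
matrices and is supported but expensive; every result reported by the
tests and the acceptance script needs it only at 132 atoms. Predictions
outside the fitted descriptor range are flagged as extrapolations.

## Problem sizes and numerical choices

The test suite and the acceptance script generate structures up to
size-4 members (≤ 4704 atoms; generation is combinatorial and fast),
eigensolve up to 1152×1152 (tests) / 900×900 (acceptance), and run one
exact 132×132 determinant — everything completes in seconds. Published
entropy tables are matched at their 4 printed decimals (tolerance 5·10⁻⁵,
all 432 cells pass); published spectral values at 10⁻³–10⁻⁵ per the
quantity's printed precision. One published complexity-table row (the
size-4 zigzag entry) is internally inconsistent — its log₂|E| value does
not correspond to its own edge count and repeats a neighbouring row — and
is excluded from comparisons.

## Limitations

- Descriptors are purely graph-theoretic; no geometry relaxation, no
  heteroatoms, no hydrogens, no ab initio validation.
- Hückel theory at the topological level (uniform α, β); charged and
  radical systems are outside scope.
- The rectangular family's published spectral rows are labelled by a single
  size; the square m = n reading is adopted consistently with the entropy
  tables and reproduces all published values.
- Templates are fixed to the three families; arbitrary user templates can
  be expanded via `expand_template` but are validated only structurally.
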