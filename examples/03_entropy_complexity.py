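"""Graph entropy and relative complexity (SIC/BIC) of the fractal families.

Every bond gets probability f(ab)/TI(G); the Shannon entropy of that
distribution (bits) measures structural diversity of the bonding
environment.  SIC and BIC normalise it by log2 of the index value and of
the bond count, making different-sized structures comparable.
"""

from coronene_fractals import FractalSpec, entropy_closed_form, entropy_table

# worked chain: first Zagreb entropy of the size-2 zigzag fractal at k=1
rep = entropy_closed_form(FractalSpec("ZHCF", 2), "M1", k=1)
print(f"ZHCF(2), M1, k=1: TI = {rep.ti_value:.0f}, "
      f"I = {rep.entropy_bits:.8f} bits (max log2|E| = {rep.log2_edges:.4f})")

# relative complexity of the size-3 member at k=2
rep3 = entropy_closed_form(FractalSpec("ZHCF", 3), "M1", k=2)
print(f"ZHCF(3), M1, k=2: I = {rep3.entropy_bits:.8f} bits, "
      f"SIC = {rep3.sic:.6f}, BIC = {rep3.bic:.6f}")

# family comparison: entropies peak at k=2 and AHCF runs slightly hotter
for family in ("ZHCF", "AHCF", "RCF"):
    frame = entropy_table(family, sizes=[2, 3], indices=["M1"])
    print(f"\n{family} first-Zagreb entropies (bits):")
    print(frame.round(4).to_string())

# SIC/BIC close to 1 mean the bond-probability distribution is nearly
# uniform: these lattices are locally homogeneous, and the armchair family
# is marginally the most complex at equal size.
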