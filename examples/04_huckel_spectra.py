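"""Hückel spectral energetics: stability descriptors from eigenvalues.

The adjacency spectrum (in beta units) yields the total pi-electron energy,
the HOMO-LUMO gap (kinetic stability), the spectral diameter, and -- through
the exact determinant -- the Kekulé structure count and Herndon resonance
energy (thermodynamic stability).
"""

from coronene_fractals import FractalSpec, generate, spectral_report

for spec in (FractalSpec("ZHCF", 1), FractalSpec("ZHCF", 2)):
    g = generate(spec)
    rep = spectral_report(g)  # Kekulé count auto-computed only for <=200 atoms
    print(f"{spec.label} ({g.n_atoms} atoms):")
    print(f"  E_pi            = {rep.e_pi:10.4f} beta")
    print(f"  HOMO-LUMO gap   = {rep.gap:10.5f} beta")
    print(f"  E_pi per atom   = {rep.e_pi_per_atom:10.4f} beta")
    print(f"  deloc. per atom = {rep.deloc_per_atom:10.6f} beta")
    if rep.kekule_count is not None:
        print(f"  Kekulé count    = {rep.kekule_count}")
        print(f"  reson. per atom = {rep.resonance_per_atom:10.6f} beta")
    print(f"  spectral diam.  = {rep.spectral_diameter:10.5f} beta")

# The gap shrinks and the delocalization energy grows from size 1 to 2:
# larger fractals are more conjugated (thermodynamically stabilised) but
# kinetically more reactive.
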