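"""Bonding parameters of a d1 vanadyl center from its EPR tensors.

Takes the axial g/A tensor of the first VO(II) complex with its two d-d band
energies and derives the full spin-Hamiltonian parameter set.
"""

from perichar import DdBands, EsrTensors, derive_all, spin_orbit_lambda

tensors = EsrTensors(g_par=1.93, g_perp=1.96, A_par=167.0, A_perp=66.0)
bands = DdBands(E1=12800.0, E2=15290.0)  # cm^-1

lam = spin_orbit_lambda(tensors.g_par, bands.E2)
row = derive_all(tensors, bands, lambda_so=lam)

print(f"lambda (spin-orbit)  = {lam:8.2f} cm^-1   (free V4+ ion: 250)")
print(f"g_o, A_o             = {row.g_o:.2f}, {row.A_o:.2f}")
print(f"G  (exchange)        = {row.G_exchange:8.2f}   (< 4: coupled binuclear centers)")
print(f"f  (distortion)      = {row.f_distortion:8.2f}")
print(f"p  (dipolar term)    = {row.p_dipolar:8.2f} x1e-4 cm^-1")
print(f"k  (Fermi contact)   = {row.k_fermi:8.3f}")
print(f"2K_par, 2K_perp      = {row.K2_par:.3f}, {row.K2_perp:.3f}  (2K_perp < 2K_par: out-of-plane pi-bonding)")
print(f"beta^2 (in-plane pi) = {row.beta2:8.4f}  (1 would be purely ionic)")

# The reduced lambda (~138 vs 250 cm^-1) and beta^2 close to but below 1
# indicate substantial V=O pi-bonding with largely ionic in-plane bonds.
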