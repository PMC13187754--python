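"""Steric descriptors on idealized ketone geometries.

Computes Boltzmann conformer weights, buried volume at the two alpha carbons
(which labels them "large"/"small"), and Sterimol L/B1/B5 down each
carbonyl->alpha bond for an idealized pinacolone (tert-butyl methyl ketone).
"""

import transelect as ts

ensemble, record = ts.generate_toy_geometries("methyl_ketone")

weights = ts.boltzmann_weights(ensemble.energies, temperature=298.15)
print(f"conformer energies (kcal/mol): {[round(float(e), 4) for e in ensemble.energies]}")
print(f"Boltzmann weights at 298 K:    {[round(float(w), 4) for w in weights]}")
# the second conformer sits RT*ln(2) above the minimum, so the weights are 2:1

roles = ts.assign_alpha_roles(record, ensemble)
print(f"\nalpha carbon {roles.large_alpha_index} is LARGE "
      f"(V_bur {roles.vbur_large:.3f}) — the tert-butyl side")
print(f"alpha carbon {roles.small_alpha_index} is SMALL "
      f"(V_bur {roles.vbur_small:.3f}) — the methyl side")

for role, alpha in (("large", roles.large_alpha_index),
                    ("small", roles.small_alpha_index)):
    sv = ts.boltzmann_averaged_sterimol(record, ensemble, alpha)
    print(f"Sterimol ({role}): L={sv.L:.2f}  B1={sv.B1:.2f}  B5={sv.B5:.2f}  (angstrom)")

# L is the substituent's reach along the bond axis; B1/B5 its thinnest and
# widest perpendicular profile. Relabelling by buried volume makes these
# columns comparable across unsymmetrical ketones.
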