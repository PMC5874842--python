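"""Flory-Huggins phase diagram for ibuprofen in Soluplus.

Estimates the interaction parameter chi from the Fedors solubility
parameters, builds the free-energy-of-mixing curve at 25 degC, and reports
the stable/metastable structure: the composition of minimum free energy,
the critical composition where demixing sets in (if any), and the spinodal
roots bounding the unstable region.
"""

import asdscreen as asd

compounds = asd.load_all_compounds()
fedors = asd.load_bundled_table("fedors")

ibu = asd.compound_parameters(compounds["IBU"], fedors)
sol = asd.compound_parameters(compounds["SOL"], fedors)

chi = asd.chi_from_solubility(
    ibu.molar_volume, ibu.delta_total, sol.delta_total
).chi
m = asd.lattice_ratio(
    asd.polymer_chain_volume(compounds["SOL"].mw, compounds["SOL"].true_density),
    ibu.molar_volume,
)
diagram = asd.classify_profile(chi, m)

print(f"chi (Fedors, 25 degC)     : {chi:.2f}")
print(f"lattice ratio m           : {m:.0f}")
print(f"profile class             : {diagram.profile_class}")
print(f"free-energy minimum at phi: {diagram.phi_min:.3f}")
print(f"critical composition      : {diagram.phi_critical}")
print(f"spinodal roots            : {[round(r, 3) for r in diagram.spinodal]}")
print(
    "\nA negative free energy across all compositions with a minimum near "
    "phi ~ 0.3 means ibuprofen mixes with Soluplus in all proportions; "
    "below the minimum the glass solution is thermodynamically stable, "
    "above it supersaturated."
)
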