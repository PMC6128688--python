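"""Liquid junction potentials and bi-ionic permeability ratios.

Computes Henderson junction potentials for the bi-ionic bath solutions used
to probe mechanosensitive-channel selectivity (KCl pipette throughout),
corrects the measured reversal potentials, converts them to permeability
ratios relative to K+, and prints the resulting permeability sequence.
A ratio near 1 for sodium means Na+ and K+ permeate equally; the calcium
ratio above 1 means Ca2+ is slightly more permeant.
"""

from mechanopatch.selectivity import (
    ErevMeasurement,
    SolutionSpec,
    bi_ionic_ratio_divalent,
    bi_ionic_ratio_monovalent,
    correct_erev,
    henderson_ljp,
    permeability_sequence,
)

pipette = SolutionSpec.from_dict({"K": (150, 1), "Cl": (150, -1)}, name="KCl")
baths = {
    "NaCl": SolutionSpec.from_dict({"Na": (150, 1), "Cl": (150, -1)}),
    "NaGluconate": SolutionSpec.from_dict({"Na": (152, 1), "gluconate": (152, -1)}),
    "CaCl2": SolutionSpec.from_dict({"Ca": (90, 2), "Cl": (180, -1)}),
    "NMDG-Cl": SolutionSpec.from_dict({"NMDG": (152, 1), "Cl": (152, -1)}),
}

print("Henderson junction potentials (bath minus pipette):")
ljps = {}
for name, bath in baths.items():
    ljps[name] = henderson_ljp(pipette, bath)
    print(f"  {name:12s}: {ljps[name]:+6.2f} mV")

# measured (uncorrected) reversal potentials in the corresponding conditions
measured = {"NaCl": 4.0, "CaCl2": 15.0}
na = correct_erev(ErevMeasurement("NaCl", measured["NaCl"], ljps["NaCl"]))
ca = correct_erev(ErevMeasurement("CaCl2", measured["CaCl2"], ljps["CaCl2"]))
print(f"\ncorrected E_rev: NaCl {na:+.2f} mV, CaCl2 {ca:+.2f} mV")

ratios = {
    "K": 1.0,
    "Na": bi_ionic_ratio_monovalent(na, 150.0, 150.0),
    "Ca": bi_ionic_ratio_divalent(ca, 150.0, 90.0),
    "NMDG": 0.05,  # nominal: E_rev collapses toward the K+ potential
}
print("\npermeability ratios relative to K+:")
for ion, r in ratios.items():
    print(f"  P_{ion}/P_K = {r:.3f}")

report = permeability_sequence(ratios, rel_tol=0.10)
print(f"\npermeability sequence: {report.sequence}")
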