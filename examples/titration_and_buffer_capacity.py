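"""Titrate a sharp nanobuffer and a chloroquine comparator, compare buffer strength.

Builds a UPS-type micelle model (apparent pKa 4.4, 10-90% protonation width
0.25 pH units, 3.2 mmol amines/g) and diprotic chloroquine, titrates 40 mg
of each (2 mg/ml in 20 ml of 150 mM NaCl) with 25-ul shots of 0.4 M HCl,
and reports the apparent pKa recovered from the equivalence points plus the
solute-only buffer-capacity fold ratio at the nanobuffer's pKa.
"""

from nanobuffer import (
    TitrationMixture,
    buffer_capacity,
    chloroquine,
    estimate_pKa,
    fold_buffer_ratio,
    simulate_titration,
    ups_species,
)

ups = ups_species(4.4)
cq = chloroquine()

curve_ups = simulate_titration(TitrationMixture(species_loads=((ups, 40.0),)), stop_pH=3.0)
curve_cq = simulate_titration(TitrationMixture(species_loads=((cq, 40.0),)), stop_pH=3.0)

print(f"UPS4.4 titration: {len(curve_ups)} points, "
      f"pH {curve_ups.pH[0]:.2f} -> {curve_ups.pH[-1]:.2f}")
print(f"recovered apparent pKa: {estimate_pKa(curve_ups):.3f} (true 4.400)")

beta_ups = buffer_capacity(curve_ups, "solute-only")
beta_cq = buffer_capacity(curve_cq, "solute-only")
ratio = fold_buffer_ratio(beta_ups, beta_cq, pH=4.4, a_stat="max")

print(f"max UPS4.4 buffer capacity: {beta_ups.beta.max():.3f} mmol H+/pH per 40 mg")
print(f"CQ buffer capacity at pH 4.4: {beta_cq.at(4.4):.2e} mmol H+/pH per 40 mg")
print(f"fold ratio (UPS max / CQ at 4.4): {ratio:.0f}")
print("The sharp cooperative transition concentrates all buffering into a")
print("~0.25 pH window around the pKa, where chloroquine barely buffers at all.")
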