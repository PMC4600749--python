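# nanobuffer

Quantitative models and analysis tools for **ultra-pH-sensitive (UPS)
nanoparticle buffers** — block-copolymer micelles that protonate
cooperatively within a <0.25 pH-unit window around a tunable apparent pKa,
and thereby clamp the luminal pH of endocytic organelles (early endosomes
~pH 6.0–6.5, late endosomes ~5.0–5.5, lysosomes ~4.0–4.5) at an
operator-chosen set point.

The package is aimed at quantitative cell biologists and nanomaterials
scientists who want to model titration and buffer-capacity data for such
"proton sponges", simulate and analyse endosomal pH-clamp kinetics, infer
per-organelle proton pumping rates, and quantify ratiometric pH imaging and
marker colocalization — all exercisable end-to-end on seeded synthetic data
with known ground truth.

## The models

**Cooperative protonation.** Each solute is a set of site groups with a
Hill-type protonated fraction

    f(pH) = 1 / (1 + 10^(n (pH − pKa)))

so the 10–90% transition spans `2·log10(9)/n` pH units; `n ≈ 7.63`
realizes the 0.25-unit micelle transition, and `n = 1` recovers classical
Henderson–Hasselbalch weak-base behaviour (used for the chloroquine and
polyethyleneimine comparators).

**Titration by charge balance.** Adding strong acid, the pH solves

    [H+] − [OH−] + Σ_g f_g(pH)·C_g = [Cl−]

with dilution-corrected concentrations (residual < 1e−12 mol/L). Buffer
capacity is β = −dn_H+/dpH by finite differences, reported per reference
solute mass, either total or with the water autoionization contribution
removed exactly ("solute-only"). The apparent pKa is the pH midway (in
added acid) between the two equivalence points (maxima of |dpH/dn|).

**Lumen clamping.** An organelle of volume V acidifies under a constant
v-ATPase flux (with stall floor) against water, an intrinsic buffer
(mol/L/pH) and the internalized micelle load, with protonation treated as
instantaneously equilibrated; each step solves a scalar proton balance, so
proton conservation is exact. While the load's protonation window is
titrated, pH dwells at the load's pKa — the clamped plateau.

**Rate inference.** protons/s/organelle =
micelles/cell × amines/micelle × consumed fraction ÷ (organelles/cell ×
clamp duration); cross-checked against the stoichiometric v-ATPase product
2 H+/ATP × 3 ATP/rotation × 2.4 rev/s × 20 pumps = 288 H+/s.

**Imaging.** Punctae detection (smoothing, quantile threshold, connected
components), background-annulus-corrected ratios R = (F1−B1)/(F2−B2),
monotone sigmoid / bi-sigmoid R→pH calibration with numerical inversion,
thresholded Mander's colocalization coefficients, and voxel-volume /
distance-transform morphometrics.

## Worked example

```python
from nanobuffer import (TitrationMixture, buffer_capacity, chloroquine,
                        estimate_pKa, fold_buffer_ratio, simulate_titration,
                        ups_species)

ups = ups_species(4.4)            # pKa 4.4, 0.25-unit width, 3.2 mmol amines/g
mix = TitrationMixture(species_loads=((ups, 40.0),))   # 2 mg/ml x 20 ml
curve = simulate_titration(mix, stop_pH=3.0)
print(estimate_pKa(curve))        # 4.391  -- recovered apparent pKa

beta_ups = buffer_capacity(curve, "solute-only")
beta_cq = buffer_capacity(
    simulate_titration(TitrationMixture(species_loads=((chloroquine(), 40.0),)), 3.0),
    "solute-only")
print(fold_buffer_ratio(beta_ups, beta_cq, pH=4.4, a_stat="max"))  # 4250.6
```

The recovered pKa (4.391) sits within ±0.05 of the model's true 4.4, and the
fold ratio says 40 mg of the sharp nanobuffer out-buffers 40 mg of
chloroquine at pH 4.4 by over three orders of magnitude — chloroquine's
diprotic pKa values (8.3, 10.4) leave it essentially unbuffered there.

The `examples/` directory holds one narrative script per capability
(titration/buffer capacity, pH-clamp simulation, rate inference,
ratiometric quantification, colocalization/morphometrics); each prints the
numbers it computes and a line on what they mean. A thin CLI mirrors the
pipeline stages (`nanobuffer titrate | buffercap | pka | simulate-lumen |
plateau | infer-rate | quantify | fit-calib | coloc | morpho |
make-synthetic`).

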