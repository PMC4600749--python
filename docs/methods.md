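# Methods

## Cooperative protonation closure

A buffering solute is a list of protonation site groups, each with an
apparent pKa, a Hill cooperativity exponent `n` and a site density in mol
protonatable sites per gram. The protonated fraction is the empirical Hill
form `f(pH) = 1/(1 + 10^(n (pH − pKa)))`. This closure is chosen because
the experimentally observable feature of a micelle-forming ultra-pH-
sensitive copolymer is the *sharpness* of its transition, not a mechanistic
isotherm: the hydrophobic phase transition cooperatively protonates the
tertiary amines within <0.25 pH units. The default exponent is therefore
fixed by the width, `n = 2·log10(9)/0.25 ≈ 7.63`, and `n = 1` reduces every
operation to classical monoprotic weak-base behaviour (checked against
textbook closed forms in the tests).

Default amine density is 3.2 mmol/g, derived from the copolymer
architecture (a PEO₁₁₄ macroinitiator plus ~80 tertiary-amine methacrylate
units per chain); exact batch compositions vary, so the value is an
overridable documented default and absolute buffer-capacity maxima are not
asserted anywhere. Comparators: chloroquine is a diprotic classical base
(pKa 8.3 and 10.4, M ≈ 320 g/mol); branched PEI is modelled only
qualitatively as ≥5 classical groups spread uniformly over pKa 4–10 with
23 mmol amines/g.

## Titration and buffer capacity

Titrations solve the exact charge balance
`[H+] − [OH−] + Σ f_g(pH) C_g = [Cl−]` by bracketed root finding on pH ∈
(0, 14); all concentrations are corrected for titrant dilution, the
background salt (150 mM NaCl) is treated as non-buffering, activity
coefficients are ignored (pH = −log10[H+]), and no CO₂/bicarbonate
chemistry is included. The charge-balance residual is required to be
< 1e−12 mol/L at every reported point. A closed-form inverse (acid needed
to reach a given pH) provides an independent oracle and lets tests build
curves on prescribed pH grids.

Buffer capacity β = −dn_H+/dpH is estimated by first differences of the
cumulative-acid coordinate assigned to interval midpoints — centred
differences on the staggered grid. In **solute-only** mode the free-proton
content `V·([H+] − [OH−])` is subtracted from the acid coordinate *before*
differencing. In the continuum limit this is identical to subtracting the
water term `ln(10)·([H+]+[OH−])·V` pointwise, but it remains exact on
coarse experimental grids: a single 25-μl increment can span more than one
pH unit in a region where the solute hardly buffers (e.g. chloroquine near
pH 4.4), and a pointwise correction applied after coarse differencing
would there overestimate the solute's β by one to two orders of magnitude.
Solute-only is the default for cross-species fold ratios because the
solvent term otherwise dominates weak comparators at acidic pH. Negative
finite-difference values (measurement noise) are clamped to zero.

The apparent pKa is the pH at the midpoint, in the added-acid coordinate,
between the two equivalence points, detected as the two most prominent
local maxima of |ΔpH/Δn| after 3-point median smoothing (edge-padded;
flat-run ties resolve to the larger acid coordinate); the pair must
bracket a region of at least two-fold lower slope, otherwise estimation
fails ("no buffering plateau", e.g. strong acid into water). At the bench
protocol (0.01 mmol per shot against a 0.128-mmol buffering plateau) the
estimator recovers true pKa values within ±0.05.

## Lumen clamp simulation

The organelle lumen is a well-mixed compartment with fixed volume
(default 6.5e−17 L, a 0.5-μm sphere), a constant-rate proton pump
(default 288 H+/s, the stoichiometric v-ATPase product) with a hard stall
floor (default pH 4.0), an optional linear leak toward cytosolic pH
(default 0), an intrinsic buffer (default 40 mmol/L/pH) and the micelle
load (default 64,000 amines per micelle). All defaults are
literature-typical values, not fitted to any particular dataset.

Protonation is assumed fast relative to pumping (quasi-static): each fixed
time step updates the delivered-proton tally and re-solves the scalar
proton balance `delivered = free(pH) + intrinsic(pH) + bound(pH)` for the
new pH. This makes proton conservation checkable to solver precision at
every sample (the tests require <0.1% relative drift, and observe ~1e−12)
and avoids a stiff ODE system. Steps that would move pH by more than 0.5
raise an error rather than silently losing the plateau structure; halving
the step changes no reported pH by more than 0.01 under test conditions.

Plateau detection: the clamp is the longest interval with the load's
protonated fraction strictly inside (0.1, 0.9). Because intrinsic
buffering is finite, even an unloaded organelle spends a short time
crossing that band; a plateau is therefore only "detected" for a non-zero
load whose interval lasts ≥10 samples *and* longer than the control's own
band-crossing time. The plateau-mean pH equals the load pKa within ±0.1
for any pKa in [4.0, 7.0] at saturating load (the band is symmetric about
the pKa and the intrinsic term is flat in pH). The activation delay is
the difference in first-crossing time below `pKa − log10(9)/n` versus the
control. The fluorescence surrogate maps the protonated (unimer) fraction
directly to the OFF-ON signal, normalized to its end-time-point value; no
FRET-efficiency model is attempted.

## Rate inference

Micelles per cell come from an affine fluorescence standard curve;
protons/s/organelle = micelles/cell × amines/micelle × consumed fraction ÷
(organelles/cell × clamp duration), with defaults 64,000 amines and 200
organelles per cell. `consumed_fraction` defaults to 1.0 (all amines
titrated); 0.8 matches the 10–90% protonation window and is the correct
choice when the clamp duration comes from the plateau detector. The
stoichiometric cross-check multiplies 2 H+/ATP × 3 ATP/rotation ×
2.4 rev/s × 20 pumps/organelle = 288 H+/s.

The end-to-end recovery study (20 synthetic cells, lognormal uptake with
CV 20%, 5% fluorescence measurement noise) is run at ~150 micelles per
organelle so that the load's in-band proton uptake dominates the
organelle's intrinsic in-band buffering; with the default intrinsic
buffer, the intrinsic contribution inflates the measured clamp duration by
~4%, a bias inside the study's 10% acceptance band and intrinsic to
clamp-based rate estimation. Absolute bench figures for the measured rate
are not reproduced — their raw fluorescence inputs are not modelled —
only the recovery property is asserted.

## Ratiometric imaging

Coordinates are 0-based; connectivity is 8 in 2D and 26 in 3D. Punctae
are detected by Gaussian smoothing (sigma in μm, converted per axis),
global quantile thresholding, connected-component labelling and a voxel-
count size filter, sorted by descending total intensity with centroid ties
lexicographic. The background of each punta is the median over an annulus
1–2 annulus-radii outside it (default 0.4–0.8 μm), excluding voxels of any
other punta — a robust stand-in for a manually chosen "nearby cytosol"
region. The ratio is R = (F1 − B1)/(F2 − B2); a non-positive denominator
flags the punta and excludes it downstream.

The R→pH calibration is a monotone descending logistic in pH
("dose–response"), or a convex mixture of two logistics sharing bottom and
top ("bi-dose–response") for probes with two transitions. Fitting is
deterministic least squares with quantile-based initialization (no random
restarts); inversion is bracketed root finding over the valid pH range,
with a 5%-of-span tolerance outside the fitted ratio range before an
extrapolation error. A calibration point on the bench is never a single
spot: the round-trip requirement (fit + inversion within 0.05 pH at 3%
intensity noise) is met with ~25 replicate measurements per calibration
pH; from 8 single noisy points a 7-parameter bi-sigmoid is
under-determined and no estimator meets that bound reliably.

Thresholded Mander's coefficients: M1 is the fraction of channel-A
intensity over voxels with A > tA that lies in voxels with B > tB
(symmetrically M2). Thresholds are user-supplied (quantile 0.95 by
default in the CLI); automated threshold selection is out of scope.
Morphometrics: vesicle volume is voxel count × voxel volume; distance to
the nucleus is the minimum over vesicle voxels of the Euclidean distance
transform of the nucleus complement (anisotropic sampling respected), so a
vesicle touching the nucleus scores 0 and the convention carries the usual
half-voxel surface ambiguity.

## Synthetic data

One master seed fans out to fixed per-scenario substreams
(`SeedSequence([seed, stream_id])`; titration 0, uptake 1, trajectories 2,
ratiometric 3, coloc 4), so outputs are byte-identical under a fixed seed
and adding a generator never perturbs existing ones. Every dataset ships a
ground-truth table sufficient to score the downstream estimators.

Emulated features: titration pH read noise (sd 0.02); per-cell lognormal
uptake (CV 20%) and affine standard-curve fluorescence with 5%
multiplicative noise; Gaussian-PSF punctae on a tilted background with
Poisson shot noise plus Gaussian read noise (2% of dynamic range); 3D
three-channel vesicle stacks where a seeded subset of cargo vesicles
carries the early-endosome-like marker. Overlap assignment is exact
(`round(fraction × n)` vesicles) rather than binomial, so the realized
overlap equals the requested one — at ~50 vesicles, binomial sampling
noise alone (~0.07 sd) would swamp the ±0.03 checks the stacks exist to
support; the ground truth records the realized fraction. The default
synthetic calibration is bi-sigmoid (transitions at pH 4.8 and 6.4),
keeping ratio sensitivity across the whole endo/lysosomal range, which is
why such probes are calibrated with a bi-dose–response in practice.

What the generators do *not* emulate: photorealistic optics
(no diffraction rings, depth-dependent PSF or spherical aberration),
photobleaching, cell segmentation, organelle motion, counter-ion fluxes or
membrane potential, and per-organelle stochastic pump counts. Passing
tests therefore demonstrate estimator correctness under the stated noise
structure, not robustness to every artefact of real microscopy.

## Problem sizes

Test and example runs use desk-scale settings chosen as the smallest sizes
that leave the asserted contrasts well-resolved: titrations of 16–30
increments; lumen simulations of 1–3 thousand steps (dt 10–25 s over
0.5–17 h of simulated time); 20-cell recovery studies; 192² two-channel
fields with 25 punctae; 8×128² three-channel stacks with 50 vesicles.

## Known limitations

- The Hill closure is empirical; no micellization free energy, ionic
  strength/activity corrections or temperature dependence.
- The pump is constant-rate with a hard stall floor; no pH-dependent pump
  thermodynamics, no counter-ion or membrane-potential coupling.
- Absolute activation half-times depend on unmodelled cell parameters
  (organelle volume and intrinsic buffering are literature-typical
  defaults), so only the ordering of half-times across pKa values is
  asserted, not their absolute values.
- Absolute buffer-capacity maxima depend on exact copolymer compositions;
  only fold ratios against comparators, as lower bounds, are asserted.
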