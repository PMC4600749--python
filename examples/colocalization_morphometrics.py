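"""Quantify marker colocalization and vesicle morphometrics on a synthetic stack.

Generates a 3D three-channel stack in which exactly 60% of cargo vesicles
carry an early-endosome-like marker, computes thresholded Mander's
coefficients, and runs voxel-volume / distance-to-nucleus morphometrics on
a labelled toy geometry.
"""

import numpy as np
from skimage.measure import label

from nanobuffer import manders, morphometrics
from nanobuffer.synthetic import gen_coloc_stacks

channels, truth = gen_coloc_stacks(n_vesicles=50, overlap_fraction=0.6, seed=3)
cargo, rab = channels["cargo"], channels["rab5_like"]
tA = float(np.quantile(cargo.intensities[cargo.intensities > 0], 0.95))
tB = float(np.quantile(rab.intensities[rab.intensities > 0], 0.95))
res = manders(cargo, rab, tA, tB)

print(f"requested overlap fraction : {truth['requested_overlap'][0]:.2f}")
print(f"measured Mander's M1       : {res.M1:.3f} (cargo intensity in marker+ voxels)")
print(f"measured Mander's M2       : {res.M2:.3f}")

# morphometrics on a labelled toy stack: a nucleus slab and two vesicles
shape = (20, 40, 40)
nucleus = np.zeros(shape, bool)
nucleus[:, :, :8] = True
vesicles = np.zeros(shape, int)
vesicles[9:12, 19:22, 7:10] = 1   # touches the nucleus face
vesicles[9:12, 19:22, 27:30] = 2  # 3x3x3 cube, 20 voxels away laterally
table = morphometrics(label(vesicles > 0, connectivity=3) , nucleus, (0.2, 0.2, 0.2))
print(table.to_string(index=False))
print("Volume = voxels x (0.2 um)^3 = 0.216 um^3 per 27-voxel cube; distance is")
print("the Euclidean distance transform minimum over each vesicle's voxels.")
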