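"""Septal penetration of the 279 keV emission through the LEHR
collimator.

Ray-traces photons from the planar source through the hexagonal hole
lattice, weighting each by its lead-survival probability and its
chance of interacting in the crystal.  The low-energy emissions are
stopped by a single septum; the 279 keV gamma typically crosses ~10
septa before detection, which is what smears its window's image.
"""

import numpy as np

from hgspect.engine import septal_penetration_survey

for E in (70.0, 134.0, 279.0):
    hist = septal_penetration_survey("lehr", E, n=150_000, seed=5)
    pen = hist[1:]
    frac = pen.sum() / hist.sum()
    mode = int(np.argmax(pen)) + 1 if pen.sum() > 0 else 0
    print(f"{E:5.0f} keV: penetrating fraction of detected weight = "
          f"{frac:6.3f}, most probable septa crossed (>=1) = {mode}")

print("\nPenetration is negligible at 70/134 keV (lead is ~0.3 mm mean")
print("free path there) but dominant at 279 keV, where the most likely")
print("detected photon crossed about ten septa.")
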