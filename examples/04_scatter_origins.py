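"""Scatter-origin decomposition of the tomographic energy spectrum.

Runs the abdominal scene with isotropic emission, tags every detected
photon with the volume class of its last inelastic scatter, convolves
the spectrum with the energy-resolution model and reports the origin
shares inside each acquisition window.  Takes ~1 minute.
"""

import math

from hgspect import digitizer as dg
from hgspect import nuclide, spectrum
from hgspect.engine import run_channels
from hgspect.geometry import abdominal_scene

scene = abdominal_scene()
isotropic = {E: math.pi for E in (70.0, 77.0, 134.0, 279.0)}
events = run_channels(scene, n_per_channel=800_000, seed=5,
                      cones=isotropic)

mixture = nuclide.default_mixture(3.7)
weights = nuclide.line_weights(mixture, 0.0)
per = {E: ev.n_histories for E, ev in events.items()}
parts = {E: spectrum.events_to_spectrum(ev) for E, ev in events.items()}
blurred = spectrum.combine_spectra(parts, weights, per).blurred(
    dg.MEASURED_RESOLUTION)

for window in dg.STUDY_WINDOWS:
    shares = spectrum.scatter_fraction_in_window(blurred, window)
    pretty = ", ".join(f"{k}: {100 * v:4.1f}%" for k, v in shares.items())
    print(f"{window.label:>7}: {pretty}")

print("\nThe 70 keV window's scatter comes from the phantom and table;")
print("the 135 keV window is contaminated from *behind* the crystal")
print("(279 keV photons backscattered in the BSC return at ~133 keV);")
print("the 280 keV window is the cleanest of the three.")
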