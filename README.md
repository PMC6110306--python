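# hgspect

A desk-scale Monte Carlo model of a dual-head clinical gamma camera and
the analysis chain needed to study planar and SPECT imaging of the
theranostic radionuclide pair **Hg-197 / Hg-197m**.

## The problem

Radiomercury emits a cluster of X-rays and gammas near 67–80 keV (both
isomers), plus 134 keV and 279 keV gammas from the metastable state
only.  Whether a standard camera can image this mixture — and how the
three clinical energy windows (70 keV ± 15%, 135 keV ± 10%,
280 keV ± 10%) each contribute — depends on physics the detector alone
cannot disentangle: septal penetration of the 279 keV emission through a
low-energy collimator, 279 keV photons backscattered *behind* the NaI
crystal re-entering at ~133 keV (indistinguishable from the true
134 keV line), and the finite energy/spatial resolution of the camera.
This package simulates all of it and re-derives the imaging figures of
merit from first principles:

- **Two-isomer source model.** Activity ratio
  `R_a = A(g)/A(m)` evolves as `R_a(t) = R_a(0)·exp((λ_m − λ_g)t)`
  (optionally with the 0.91 isomeric-transition ingrowth via the Bateman
  solution); mono-energetic simulations at 70/77/134/279 keV are
  combined with per-line intensity weights at the acquisition-time
  ratio, so one simulation serves every measurement time.
- **Photon transport.** Tabulated photoelectric/incoherent attenuation,
  Klein–Nishina Compton sampling, lead K fluorescence, an exact
  chord-segmentation tracer for the hexagonal-hole collimator lattice,
  and a layered head (collimator, Al cover, 9.5 mm NaI, light guide,
  150 mm backscatter compartment, lead shielding).
- **Digitizer.** Linear FWHM(E) energy-resolution model (two-point fit
  through 9.6% at 134 keV and 9.1% at 279 keV), window acceptance as
  the normal-CDF overlap `Φ((U−E)/σ(E)) − Φ((L−E)/σ(E))`, and an
  isotropic Gaussian intrinsic LSF (σ = 1.82 mm ↔ FWHM 4.29 mm).
- **Bar-phantom MTF analysis.** Modulation
  `M = (A_max − A_min)/(A_max + A_min)` from Gaussian peak/trough fits,
  intrinsic MTF as the ratio `M_data(ν)/M_sim(ν)`, Gaussian MTF fit
  with width ω and `σ = 1/(2πω)`.
- **Tomography.** Dual-head acquisition over 180° in the co-rotating
  phantom frame, geometric-mean conjugate views, OSEM (2 subsets,
  8 iterations) with an exact-adjoint rotate-and-sum projector, and
  centroid/width metrics for the three cylindrical sources.
- **Synthetic data.** Pseudo-measurements = simulation ⊗ intrinsic blur
  + Poisson noise, with the injected truth recorded for recovery tests.

## A worked example

```
$ python examples/02_planar_bar_phantom.py
window composition of the combined image:
    70keV:  75.9 %
   135keV:   8.2 %
   280keV:  15.9 %

quadrant modulation (None = no bar pattern locatable):
     4 mm bars: unresolved
     6 mm bars: 0.157
     8 mm bars: 0.344
    10 mm bars: 0.521

smallest resolved period: 6.0 mm
```

The 70 keV window carries the bulk of the planar image at activity
ratio 5.92; the 280 keV window contributes a septal-penetration haze
(~16% of the counts), the 135 keV window a backscatter-contaminated
~8%; and the
finest bar pattern the LEHR collimator resolves after the full
resolution model is the 6 mm quadrant.  The other examples cover decay
weighting, septal penetration (`03`: the most probable detected
279 keV photon crossed ~10 septa), scatter-origin decomposition (`04`),
SPECT reconstruction (`05`) and intrinsic-resolution recovery from
pseudo-measurements (`06`).

A thin CLI wraps the same workflows:
`hgspect run-planar --collimator lehr --out report.json`,
`hgspect septal-survey`, `hgspect run-spect`, `hgspect simulate`.

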