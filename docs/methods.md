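# Methods

This note documents the physical model, the parameter choices and the
numerical decisions behind `hgspect`, and what the test suite does and
does not demonstrate.

## Source model

Mercury-197 is modelled as two coupled states: the ground state
(T½ = 64.1 h, EC to Au-197) and the metastable state (T½ = 23.8 h,
branching 0.91 to the ground state by internal transition, 0.09 by EC).
The activity ratio `R_a = A(g)/A(m)` at time t is, by default, the
independent-decay expression `R_a(0)·exp((λ_m − λ_g)t)`; a `bateman`
mode adds the ground-state ingrowth from the isomeric transition.  The
simple mode is the default because a transferable ratio measured by
gamma spectroscopy is naturally propagated with the bare half-lives;
the two modes differ by ~12% after four days.

Photon emissions are grouped onto four simulated channels — 70, 77,
134 and 279 keV.  The 70 keV channel absorbs the Au and Hg Kα X-rays
(67.0–70.8 keV); the 77 keV channel the 77.35 keV gamma and the Kβ
X-rays of both isomers (78–80 keV); 134 and 279 keV are the metastable
gammas.  Per-line intensities (photons per disintegration) are
approximate external constants from standard evaluated nuclear data,
shipped in `data/hg197m.yaml` and overridable; the sub-percent 191 and
269 keV ground-state gammas are omitted.  Channel images and spectra
are combined as `Σ_E w_E(t) · (tally_E / n_histories_E)` with
`w_E(t) = Σ_lines intensity · activity_share(parent, t)`, so a single
set of mono-energetic event lists can be re-weighted to any
acquisition time.

## Transport physics

Photons undergo photoelectric absorption and incoherent (Compton)
scattering; coherent scattering, Doppler broadening and electron
transport are not modelled (deposits are local).  Compton kinematics
are free-electron Klein–Nishina, sampled by rejection on a uniform
cos θ proposal.  Photoelectric absorption in lead above the 88.005 keV
K edge re-emits a characteristic K X-ray (74.97/72.80/84.94/87.32 keV)
isotropically with probability 0.75 — the product of the K-shell
vacancy share and the K fluorescence yield — because collimator lead
X-rays fall inside the 70 keV acquisition window.

Attenuation coefficients ship as per-material CSV tables
(20–700 keV).  The totals are anchored at standard reference
(NIST XCOM) grid values with coherent scattering folded into the
absorption column; the incoherent column is the Klein–Nishina cross
section scaled by Z/A; NaI photoelectric follows an E⁻³ law anchored
at 100 keV with the iodine K edge (jump ratio 5.6; K-escape from the
crystal is not modelled).  Log–log interpolation reproduces the table
nodes exactly.  Materials: lead, NaI, water, PMMA, aluminium, air, and
a water-equivalent hydrocarbon at 1.05 g/cm³ for the backscatter
compartment.

*Consequence of the free-electron approximation*: small-angle
incoherent scatter is overestimated (binding suppression is absent).
The measured in-window scatter fraction of the 280 keV window in the
tomographic scene is ~0.2 in this model — roughly half from forward
scatter in the phantom, half from the collimator — where a
bound-electron simulation reports the window as largely scatter-free.
The qualitative origin structure (phantom-dominated 70 keV window,
backscatter-dominated 135 keV window) is insensitive to this.

## Geometry

Each camera head is a stack of cuboid layers from the collimator
entrance inwards: collimator, 1.5 mm Al cover, 9.5 mm NaI crystal,
9 mm PMMA-equivalent light guide, 150 mm backscatter compartment and
20 mm lead back/side shielding, with a 40.6 × 54 cm face.  The
collimator is an ideal triangular lattice of flat-topped hexagonal
holes (flat sides along the detector x axis, one hole centred at the
origin; pitch = flat-to-flat + septal thickness).  LEHR: length 27.0,
hole circum-diameter 1.22, septa 0.152 mm; HEGP: 58.4 / 3.81 /
1.730 mm.  Rays through the collimator are segmented exactly into
hole/septum chords by clipping against the hexagonal prisms; septa
crossed are counted as maximal lead segments entered on the
source-to-first-crystal-deposit path, including post-scatter segments.

The planar scene is a 12 × 8 cm, 4 mm deep aqueous source lying
directly on the four-quadrant bar mask (periods 4/6/8/10 mm, 50% duty,
stripes along y, phase anchored at each quadrant's inner edge) at the
collimator face.  The mask is a perfectly opaque, infinitely thin
plane: at 70–80 keV even 1 mm of lead transmits essentially nothing,
and bar-scatter is neglected.

The abdominal scene is a 30 × 20 × 8 cm PMMA slab holding three water
cylinders along the axial direction — V25 (⌀27 mm), V11 (⌀19 mm) and
SYR (⌀5 mm) at trans-axial offsets −70/0/+65 mm — on a 2 cm
PMMA-equivalent patient table.  Activity concentrations default to
0.5 / 1.0 / 2.0 (arbitrary units); the study filled the containers
with unspecified "varying" concentrations, and none of the reported
metrics depend on the absolute values.  Two opposed LEHR heads face
the phantom at 20 cm from the rotation axis; gantry rotation is
implemented by counter-rotating the phantom and table.

## Monte Carlo engine

Histories are tracked analytically from region boundary to region
boundary (no voxelisation): exponential free paths in homogeneous
regions, exact chord segmentation in the collimator, a 20 keV tracking
cutoff.  All crystal deposits of one history pool into a single
detection event (energy-weighted centroid), mirroring one-pulse
readout.  Events carry the scatter-origin class of the last inelastic
interaction before the first crystal deposit (direct / phantom /
upstream / downstream, with lead fluorescence counted as an inelastic
redirection) and the septa-crossed count.  Weight bookkeeping is
exact: emitted = masked + absorbed + escaped + cutoff, asserted in
tests to 1e−9.

Angular importance sampling restricts emission to a cone (planar) or
double cone (tomographic) about the detector normal, carrying the
solid-angle fraction as weight.  Default half-angles per channel
(planar 0.15/0.15/0.6/π⁄2 rad, tomographic 0.12/0.12/0.35/0.9 rad)
are chosen so that excluded directions cannot contribute at the
respective energy: at 70 keV the lead mean free path is 0.26 mm, so
detection beyond a few degrees of obliquity is suppressed by factors
< 1e−5, while the 279 keV channel samples the full hemisphere.
Unbiasedness is tested by comparing detection rates between cone
settings.  Scatter-sensitive analyses (spectrum decomposition) use
isotropic emission.

## Digitizer

The energy model is an affine absolute-FWHM fit; the default is the
two-point model through (134 keV, 9.6%) and (279 keV, 9.1%):
FWHM(E) = 0.0864·E + 1.29 keV, which evaluates to 9.56% at 140 keV.
It is used in two separate ways, never mixed: spectra are convolved
bin-by-bin with Gaussians of σ(E) (bin width must be ≤ FWHM/5;
spectra default to 1.05 keV bins on a 50–350 keV axis, the floor
sitting below the lowest window edge), while for imaging each event is
weighted by the CDF overlap of the window with a Gaussian at its
deposit energy.  Windows follow the clinical convention
centre·(1 ± width/2).  The intrinsic spatial blur is an isotropic
Gaussian (σ = 1.82 mm default, FWHM 4.29 mm), applied to images with
an 8σ-truncated kernel so the Gaussian semigroup holds to ~1e−7.

## Bar-phantom modulation analysis

Quadrant profiles are projections along the stripe direction; each
expected extremum (peaks at phase + k·p, troughs half a period later,
phase known from the mask) is fitted with a Gaussian plus constant in
a ±p/4 window, and `M = (A_max − A_min)/(A_max + A_min)` from the mean
fitted values.  Windows with no internal contrast (plateaus of an
unblurred square wave) contribute their plateau value at the expected
position.

Two validity checks guard against Moiré aliasing, which is physically
present: the hole lattice samples the image at an effective 4.36 mm
x-spacing (LEHR 1.05 mm), so the HEGP 6 and 8 mm quadrants alias to
apparent patterns near 15.9 and 9.6 mm.  A quadrant is only "resolved"
if (1) the fitted peak positions are consistent with the expected grid
(residual spread ≤ p/6, at least half the expected peaks located), and
(2) the phase-locked fundamental amplitude agrees between the two
halves of the profile (ratio ≥ 0.4) — an alias beats against the bar
grid and flips phase along the quadrant, a genuine pattern does not.
Both checks implement the requirement that peaks sit at the expected
half-period spacing; neither involves the modulation threshold.

The resolvability threshold defaults to 0.1 (the conventional limiting
modulation).  At the packaged study conditions the LEHR classification
is stable for thresholds in [0.05, 0.15]; the 6 mm modulation after
the full resolution model is ≈ 0.15, so a threshold as high as 0.2
would flip that quadrant.  Intrinsic MTF ratios above 1 are clipped to
1 with a warning before the Gaussian fit `exp(−ν²/(2ω²))`;
σ = 1/(2πω).  The recovery tests blur a band-limited bar image
(harmonic-rich ideal masks bias the Gaussian-MTF fit low, because
square-wave modulation is not the fundamental's attenuation).

## Tomography

Projections are acquired per gantry angle by running the four channels
in the rotated frame; posterior-head views are recorded in the
mirrored detector frame and enter reconstruction as gantry angle
+180°, giving 360° coverage from a 180° rotation.  Reconstruction is
plain per-slice OSEM with a pixel-driven rotate-and-sum projector
whose backprojector is the exact matrix transpose — this makes the
subsets=1 case true MLEM with guaranteed likelihood ascent, asserted
numerically.  No attenuation, scatter or collimator-resolution
modelling is applied, matching the study's reconstruction settings;
the vendor's proprietary resolution-recovering algorithm is
deliberately replaced by this generic OSEM.

Source metrics average the reconstructed axial slice band (the
cylinders are uniform along it), refine centroids by local centre of
mass, and report FWHM along the centroid-connecting profiles.
Without resolution recovery the converged OSEM estimate is the
PSF-blurred object, and a disk convolved with a comparable 2-D
Gaussian has a profile FWHM *below* its diameter (edge-curvature
effect): at the ~10 mm system PSF of this geometry the 27 mm vial
reconstructs at ≈ 25 mm (−8%), the 19 mm vial at ≈ 16 mm (−16%), and
the 5 mm syringe at ≈ 11 mm (> 2× its size).  The syringe bound and
the source positions/distances are the robust metrics here; the V11
width lies outside a ±10% band for any algorithm that does not model
the collimator response, which is a property of the documented OSEM
substitution, not a statistical artefact.

## Synthetic data

Pseudo-measurements degrade simulation output exactly the way the
analysis assumes real data to differ from raw simulation: intrinsic
Gaussian blur plus Poisson counting noise at a chosen count level,
with the injected σ, scale and seed recorded.  They do not emulate
uniformity or linearity artefacts of a real camera, energy
nonlinearity, or dead time; passing recovery tests therefore validates
the estimator chain, not the absence of such artefacts in real data.

## Problem sizes and determinism

Default desk-scale runs: planar studies use a few million histories
per channel (≈ 0.5–1 minute per collimator), the septal survey 600 k
rays, SPECT acquisitions 45 gantry positions at a 64² matrix with
6.39 mm pixels (half the clinical 128²/3.195 mm, flagged in the
config).  Every run derives all randomness from a single integer seed
and records it, with per-chunk and per-angle seeds spawned
deterministically; fixed-seed reruns are bitwise reproducible.

## Known limitations

- Free-electron Compton and missing coherent scatter (see above).
- Attenuation tables are anchored, not full evaluations; between-node
  log–log interpolation is accurate to a few percent.
- The bar mask is opaque and thin; bar scatter and partial
  transmission are absent.
- No dead time, pile-up, PMT-level optics or energy nonlinearity.
- The septa-crossed distribution is broad; its mode estimate retains
  ±1 bin of statistical play at the default survey size.
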