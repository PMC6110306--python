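# Default Hg-197 / Hg-197m source description.
#
# Half-lives and the metastable->ground branching fraction are the values
# used throughout this package (64.1 h, 23.8 h, 0.91).  Per-line photon
# intensities (photons per disintegration) are external constants taken
# from standard evaluated nuclear data (ENSDF/NuDat); they are approximate
# and can be overridden by supplying a modified copy of this file.
#
# Each emission line is assigned to one of the mono-energetic simulation
# channels (70, 77, 134, 279 keV).  The 77 keV channel also absorbs the
# K-beta X-rays of both isomers (average energies 78-80 keV), which are
# represented by 77 keV photons.
isomers:
  - name: ground          # Hg-197, EC to Au-197
    half_life_h: 64.1
  - name: metastable      # Hg-197m, IT to Hg-197 (91%) / EC to Au-197m (9%)
    half_life_h: 23.8
    branching_to_ground: 0.91
activity_ratio_ref: 1.0   # R_a = A(ground)/A(metastable) at reference time
reference_time_h: 0.0
lines:
  # ground state: Au K X-rays + 77.35 keV gamma
  - {energy_keV: 66.99, intensity: 0.225, parent: ground, label: "Au Ka2"}
  - {energy_keV: 68.81, intensity: 0.382, parent: ground, label: "Au Ka1"}
  - {energy_keV: 78.0,  intensity: 0.135, parent: ground, label: "Au Kb"}
  - {energy_keV: 77.35, intensity: 0.187, parent: ground, label: "gamma 77"}
  # metastable state: Hg K X-rays (from converted IT cascade) + gammas
  - {energy_keV: 68.90, intensity: 0.158, parent: metastable, label: "Hg Ka2"}
  - {energy_keV: 70.82, intensity: 0.270, parent: metastable, label: "Hg Ka1"}
  - {energy_keV: 80.2,  intensity: 0.098, parent: metastable, label: "Hg Kb"}
  - {energy_keV: 133.99, intensity: 0.334, parent: metastable, label: "gamma 134"}
  - {energy_keV: 278.85, intensity: 0.060, parent: metastable, label: "gamma 279"}
channel_assignment:
  # emission line label -> simulated channel energy (keV)
  "Au Ka2": 70
  "Au Ka1": 70
  "Hg Ka2": 70
  "Hg Ka1": 70
  "Au Kb": 77
  "Hg Kb": 77
  "gamma 77": 77
  "gamma 134": 134
  "gamma 279": 279
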