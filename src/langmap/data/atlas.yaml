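# Region-of-interest atlas and network identification rules.
#
# Each region is a set of spheres [x, y, z, radius_mm, hemisphere], with
# hemisphere L (x < 0), R (x > 0), or M (midline).  Language-system centres
# follow the group peak coordinates of the cohort this pipeline models;
# attention/control-system centres are literature-conventional choices made
# for this package so the rule engine has explicit, reproducible geometry.
regions:
  MTG:        # posterior middle temporal gyrus, near the superior temporal sulcus
    - [-63, -28,  -9, 12, L]
    - [ 62, -30, -11, 12, R]
  ANG:        # angular gyrus
    - [-54, -55,  30, 12, L]
    - [ 57, -55,  36, 12, R]
  TP:         # temporal pole
    - [-51,  21, -11, 12, L]
    - [ 51,  14, -12, 12, R]
  IFG:        # inferior frontal gyrus (pars orbitalis / triangularis)
    - [-47,  27,  -9, 12, L]
    - [-54,  21,   6, 12, L]
    - [ 51,  30, -11, 12, R]
    - [ 50,  27,  -8, 12, R]
  SMA_preSMA: # posterior medial frontal / pre-supplementary motor area
    - [ -6,  17,  64, 12, M]
    - [ -9,  17,  60, 12, M]
  dACC:       # dorsal anterior cingulate
    - [ -3,  27,  28, 12, M]
  AIFO:       # anterior insula / frontal operculum
    - [-38,  18,  -9, 12, L]
    - [ 42,  12,  -8, 12, R]
  SMG_TPJ:    # supramarginal gyrus / temporo-parietal junction (VAN marker)
    - [-58, -44,  20, 12, L]
    - [ 58, -44,  20, 12, R]
  IPS:        # superior intraparietal sulcus (DAN marker)
    - [-26, -60,  52, 12, L]
    - [ 26, -60,  52, 12, R]
  FEF:        # frontal eye field (DAN marker)
    - [-26,  -8,  52, 12, L]
    - [ 26,  -8,  52, 12, R]
  LOC:        # lateral occipital cortex / MT+ (DAN marker)
    - [-46, -68,   0, 12, L]
    - [ 46, -68,   0, 12, R]
  DLPFC:      # dorsolateral prefrontal cortex (frontoparietal-control marker)
    - [-42,  28,  34, 12, L]
    - [ 42,  28,  34, 12, R]
  OFC:        # anterior orbitofrontal cortex (frontoparietal-control marker)
    - [-36,  52,  -8, 12, L]
    - [ 36,  52,  -8, 12, R]

# A component satisfies a rule when every required region contains at least
# one peak (unilaterally or bilaterally) and no exclusion region does.  The
# angular gyrus vs supramarginal/TPJ opposition is the LANG-vs-VAN
# discriminator; DLPFC/orbitofrontal dominance marks the lateral
# frontoparietal control network.
rules:
  - network: LANG
    required: [MTG, IFG, ANG]
    exclusion: []
    notes: language network at rest; MTG + IFG + ANG, unilateral or bilateral
  - network: VAN
    required: [SMG_TPJ, IFG]
    exclusion: [ANG]
    notes: ventral attention; supramarginal/TPJ instead of angular gyrus
  - network: SN
    required: [dACC, SMA_preSMA, AIFO]
    exclusion: []
    notes: salience; cingulo-opercular triad
  - network: DAN
    required: [IPS, FEF, LOC]
    exclusion: []
    notes: dorsal attention; intraparietal sulcus + frontal eye field + lateral occipital
  - network: lFPC
    required: [DLPFC, OFC]
    exclusion: [MTG]
    notes: frontoparietal control; massive DLPFC and orbitofrontal activity, no posterior MTG
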