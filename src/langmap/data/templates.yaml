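# Default network templates for the synthetic BOLD generator.
#
# Each node is [x, y, z, amplitude, sigma_mm] in MNI millimetres.  LANG and
# SN node coordinates are the group peaks of the language and
# cingulo-opercular systems reported for this cohort; VAN, DAN, lFPC, DMN
# and VIS coordinates are literature-conventional choices made for this
# package (implementation conventions, not claims about any cohort).
LANG:
  - [-63, -28,  -9, 1.0, 6.0]   # L middle temporal gyrus
  - [-54, -55,  30, 1.0, 6.0]   # L angular gyrus
  - [-47,  27,  -9, 1.0, 6.0]   # L inferior frontal gyrus (p. orbitalis)
  - [ -6,  17,  64, 1.0, 6.0]   # L posterior medial frontal
  - [ 24, -76, -30, 1.0, 6.0]   # R cerebellum (crus 1)
VAN:
  - [ 58, -44,  20, 1.0, 6.0]   # R supramarginal gyrus / temporo-parietal junction
  - [ 50,  27,  -8, 1.0, 6.0]   # R inferior frontal gyrus / ventral frontal cortex
  - [-58, -44,  20, 0.5, 6.0]   # L supramarginal gyrus (weaker, VAN is right-dominant)
SN:
  - [ -3,  27,  28, 1.0, 6.0]   # dorsal anterior cingulate
  - [ -9,  17,  60, 1.0, 6.0]   # posterior pre-SMA
  - [-38,  18,  -9, 1.0, 6.0]   # L anterior insula / frontal operculum
  - [ 42,  12,  -8, 1.0, 6.0]   # R anterior insula / frontal operculum
DAN:
  - [-26, -60,  52, 1.0, 6.0]   # L superior intraparietal sulcus
  - [ 26, -60,  52, 1.0, 6.0]   # R superior intraparietal sulcus
  - [-26,  -8,  52, 1.0, 6.0]   # L frontal eye field
  - [ 26,  -8,  52, 1.0, 6.0]   # R frontal eye field
  - [ 46, -68,   0, 1.0, 6.0]   # R lateral occipital cortex (MT+)
lFPC:
  - [-42,  28,  34, 1.0, 6.0]   # L dorsolateral prefrontal cortex
  - [-36,  52,  -8, 1.0, 6.0]   # L anterior orbitofrontal cortex
  - [-44, -60,  48, 1.0, 6.0]   # L superior inferior-parietal lobule (above ANG)
DMN:
  - [  0, -52,  26, 1.0, 6.0]   # posterior cingulate / precuneus
  - [  0,  52,  -6, 1.0, 6.0]   # medial prefrontal cortex
  - [-46, -66,  32, 0.7, 6.0]   # L lateral parietal
  - [ 46, -66,  32, 0.7, 6.0]   # R lateral parietal
VIS:
  - [  0, -84,   6, 1.0, 6.0]   # calcarine / primary visual
  - [-22, -74,  12, 0.7, 6.0]   # L extrastriate
  - [ 22, -74,  12, 0.7, 6.0]   # R extrastriate
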