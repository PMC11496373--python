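# Synthetic calibration of the top-height equation constants.
#
# These are NOT the published Alberta growth-and-yield fits (which are not
# reproduced here); they are package-supplied values calibrated so that the
# equations are strictly increasing in total age (1..80 yr) and in site
# index (0.05..80 m), satisfy HT(50) = SI exactly, and trace realistic
# boreal-conifer height trajectories (for SI 18 m: ~0.3 m at age 3,
# ~8 m (spruce, age 16) / ~12.6 m (pine, age 32) at the common age).
# Supply regionally fitted constants for operational use.
white_spruce:
  b1: 12.125
  b2: -4.45
  b3: -0.25
  b4: 0.15
  common_age: 16
lodgepole_pine:
  f1: 12.655
  f2: -6.01
  f3: -0.70
  f4: 0.15
  common_age: 32
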