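{
 "description": "12 in-plane background-ROI centres as fractions (x/a, y/b) of the fixture body semi-axes; NU-2-style layout adapted to the synthetic fixture so all diameters keep 15 mm clearance from edge and spheres.",
 "positions_frac": [
  [
   0.7909,
   0.0
  ],
  [
   0.7233,
   0.2972
  ],
  [
   0.5519,
   0.5262
  ],
  [
   0.0617,
   0.7324
  ],
  [
   -0.3387,
   0.6638
  ],
  [
   -0.5617,
   0.5172
  ],
  [
   -0.7287,
   0.2855
  ],
  [
   -0.7908,
   -0.0127
  ],
  [
   -0.7176,
   -0.3089
  ],
  [
   -0.542,
   -0.535
  ],
  [
   -0.3137,
   -0.6743
  ],
  [
   -0.0754,
   -0.7313
  ]
 ]
}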