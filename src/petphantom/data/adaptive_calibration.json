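{
 "volumes_cc": [
  1.7485411887924323,
  4.163591478349807,
  8.150495357687353,
  14.099619869653894,
  33.46053831172144
 ],
 "lb_levels": [
  3.0,
  5.0,
  10.0,
  20.0,
  30.0
 ],
 "eps": [
  [
   0.66,
   0.64,
   0.64,
   0.64,
   0.64
  ],
  [
   0.6,
   0.59,
   0.59,
   0.59,
   0.59
  ],
  [
   0.58,
   0.58,
   0.58,
   0.58,
   0.58
  ],
  [
   0.53,
   0.53,
   0.53,
   0.53,
   0.53
  ],
  [
   0.5,
   0.5,
   0.5,
   0.5,
   0.5
  ]
 ]
}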