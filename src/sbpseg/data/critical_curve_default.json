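{
 "alpha": 0.01,
 "l0": 33,
 "lengths": [
  66,
  94,
  132,
  188,
  266,
  376,
  532,
  752,
  1063,
  1504,
  2048,
  2896,
  4096,
  5793,
  8192,
  11585,
  16384
 ],
 "values": [
  0.3939393939393939,
  0.386594569719282,
  0.36525303132011855,
  0.3337560807314128,
  0.3329470672389127,
  0.3123458318165272,
  0.3123458318165272,
  0.3071464853350811,
  0.3071464853350811,
  0.3071464853350811,
  0.3070762404809149,
  0.3048455194376046,
  0.29685983151487577,
  0.2929340776074278,
  0.2929340776074278,
  0.2929340776074278,
  0.2888150664494618
 ],
 "provenance": {
  "method": "monte-carlo maximal-KS scan on i.i.d. standard Gaussian series",
  "n_null": [
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   2000,
   1000,
   1000,
   1000,
   500,
   500,
   500
  ],
  "seed": 12345,
  "quantile_method": "linear",
  "per_point_seed": "default_rng([seed, N])",
  "note": "packaged default; per-point RNG default_rng([seed, N]) makes each grid point independently reproducible"
 }
}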