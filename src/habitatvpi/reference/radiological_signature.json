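{
 "format": "habitatvpi.signature.v1",
 "name": "radiological",
 "intercept": -3.164,
 "coefficients": {
  "solid_component_diameter": 0.162,
  "SPL": 0.063
 },
 "cutoff": 0.348,
 "feature_stats": {}
}
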