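{
 "format": "habitatvpi.signature.v1",
 "name": "habitat",
 "intercept": -1.032,
 "coefficients": {
  "Habitat1_firstorder_Skewness": -0.706,
  "Habitat1_GLDM_SmallDependenceEmphasis": 0.504,
  "Habitat2_NGTDM_Busyness": -1.234,
  "Habitat3_GLCM_ClusterProminence": -0.826,
  "Habitat3_NGTDM_Contrast": -0.712
 },
 "cutoff": 0.476,
 "feature_stats": {}
}
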