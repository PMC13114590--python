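{
 "format": "habitatvpi.signature.v1",
 "name": "radiomic",
 "intercept": -0.876,
 "coefficients": {
  "GLCM_ClusterShade": -1.036,
  "GLDM_LargeDependenceEmphasis": 0.621,
  "GLDM_LargeDependenceLowGrayLevelEmphasis": -1.864
 },
 "cutoff": 0.358,
 "feature_stats": {}
}
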