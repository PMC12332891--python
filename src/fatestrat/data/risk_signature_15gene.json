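{
  "name": "risk_signature_15gene",
  "provenance": "packaged",
  "description": "15-gene malignant-cell-fate prognostic risk signature for breast cancer. Risk score = sum of beta_i * expression_i.",
  "coefficients": [
    ["RNASE1", 0.1134],
    ["SLIT3", 0.1126],
    ["GBP1", -0.2472],
    ["ACKR3", 0.0747],
    ["CD52", -0.0669],
    ["MZT2A", -0.0695],
    ["RGS3", 0.0646],
    ["B4GALT1", -0.1491],
    ["SEMA3B", -0.1600],
    ["RBBP8", -0.0620],
    ["RTN4", 0.2354],
    ["TPRG1", -0.0776],
    ["PKIB", 0.0440],
    ["SCUBE2", -0.0248],
    ["NDUFB1", -0.2030]
  ]
}
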