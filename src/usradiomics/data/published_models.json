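{
  "total": {
    "intercept": 0.3715483,
    "coefficients": {
      "mad_6_0": -0.0179227,
      "sv_43_0": -0.0202624,
      "HL_ene_1_0": -0.0000068,
      "HL_rln_48_0": -0.0000041,
      "LL_uni_13_0": -0.0769504,
      "LL_lrlgle_54_0": -0.0013692,
      "LL_se_42_45": 0.0025444,
      "LL_se_42_90": 0.5554316
    },
    "lambda_min": 0.03229,
    "lambda_1se": 0.08984,
    "lambda_rule": "1se"
  },
  "cptc_lt20": {
    "intercept": -2.2001791,
    "coefficients": {
      "LH_srlgle_52_0": 11.4205518,
      "LL_uni_13_0": -0.7666155,
      "LL_se_42_90": 0.8461400,
      "LL_lrhgle_55_90": -0.0001180
    },
    "lambda_min": 0.0329208,
    "lambda_1se": 0.072595,
    "lambda_rule": "1se"
  }
}
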