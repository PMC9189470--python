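{
  "Gamma_true": [
    0.0010464857128455176,
    -0.015298736884742327,
    -0.012166218161042078,
    -0.02073565387668976,
    -0.0038407130550534036,
    -0.00954994028698323,
    0.0052229449833261785,
    0.014095399507011514
  ],
  "alpha": [
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0
  ],
  "alpha_oriented": [
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0
  ],
  "config": {
    "beta_causal": -0.116,
    "inside_violation": false,
    "maf_range": [
      0.1,
      0.5
    ],
    "n_exposure": 7827,
    "n_outcome_cases": 6000,
    "n_outcome_controls": 195000,
    "n_snps": 8,
    "outliers": {
      "count": 0,
      "displacement_se": 0.0
    },
    "palindromic_fraction": 0.0,
    "pleiotropy": {
      "kind": "none",
      "mean": 0.0,
      "sd": 0.0
    },
    "seed": 20220405,
    "target_r2": 0.0265
  },
  "gamma": [
    -0.009021428559013082,
    0.1318856627995028,
    0.10488119104346619,
    0.17875563686801516,
    0.03310959530218451,
    0.08232707143951061,
    -0.04502538778729464,
    -0.1215120647156165
  ],
  "maf": [
    0.19577109684093622,
    0.1841929415315977,
    0.20475948395187427,
    0.11709145527726116,
    0.29156752414353815,
    0.3019205857299778,
    0.4431118202787606,
    0.35334107916888846
  ],
  "n_eff_outcome": 23283.582089552237,
  "realized_r2": 0.026500000000000003
}
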