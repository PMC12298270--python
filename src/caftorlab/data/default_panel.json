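{
  "analytes": [
    {
      "name": "IVA",
      "lloq": 0.1,
      "uloq": 20.0,
      "calibrator_levels": [0.1, 1.0, 5.0, 10.0, 15.0, 20.0],
      "qc_levels": {"low": 0.3, "medium": 8.0, "high": 18.0},
      "internal_standard": "IVA-d9",
      "mrm_quantifier": "393.2 -> 172.0",
      "mrm_qualifier": "393.2 -> 337.1",
      "beta": 0.0866
    },
    {
      "name": "TEZ",
      "lloq": 0.1,
      "uloq": 20.0,
      "calibrator_levels": [0.1, 1.0, 5.0, 10.0, 15.0, 20.0],
      "qc_levels": {"low": 0.3, "medium": 8.0, "high": 18.0},
      "internal_standard": "TEZ-d4",
      "mrm_quantifier": "521.2 -> 449.1",
      "mrm_qualifier": "521.2 -> 131.0",
      "beta": null
    },
    {
      "name": "ELX",
      "lloq": 0.1,
      "uloq": 20.0,
      "calibrator_levels": [0.1, 1.0, 5.0, 10.0, 15.0, 20.0],
      "qc_levels": {"low": 0.3, "medium": 8.0, "high": 18.0},
      "internal_standard": "ELX-d3",
      "mrm_quantifier": "598.2 -> 55.1",
      "mrm_qualifier": "598.2 -> 422.2",
      "beta": null
    }
  ]
}
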