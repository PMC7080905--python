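{
  "name": "f18-peptide-release",
  "criteria": {
    "molar_activity_gbq_umol": {
      "min": 44
    },
    "radiochemical_purity_pct": {
      "min": 90
    },
    "ethanol_ppm": {
      "max": 100000
    },
    "acetonitrile_ppm": {
      "max": 400
    },
    "dmf_ppm": {
      "max": 880
    },
    "pyridazine_ppm": {
      "max": 400
    },
    "half_life_min": {
      "min": 105,
      "max": 115
    },
    "ph": {
      "min": 4.5,
      "max": 7.5
    },
    "radiochemical_identity_pct": {
      "min": 90,
      "max": 110
    },
    "ascorbic_acid_mg_l": {
      "max": 20000
    },
    "endotoxin_eu_ml": {
      "max": 10.0
    },
    "radionuclidic_purity_pct": {
      "min": 99.5
    },
    "filter_integrity": {
      "qualitative_expected": "pass"
    },
    "appearance": {
      "qualitative_expected": "pass"
    },
    "sterility": {
      "qualitative_expected": "pass"
    }
  }
}
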