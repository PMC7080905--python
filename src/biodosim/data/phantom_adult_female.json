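{
  "name": "ADULT-F",
  "body_mass_g": 60000.0,
  "organs": {
    "pancreas": 120.0,
    "stomach": 140.0,
    "lungs": 950.0,
    "blood": 4100.0,
    "liver": 1400.0,
    "kidneys": 275.0,
    "small_intestine": 600.0,
    "urine": 200.0,
    "gallbladder": 8.0,
    "large_intestine": 360.0,
    "heart": 250.0,
    "spleen": 130.0,
    "adrenals": 13.0,
    "thyroid": 17.0,
    "bone": 7800.0,
    "muscle": 17500.0,
    "skin": 2300.0,
    "fat": 18000.0,
    "brain": 1300.0
  }
}
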