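{
  "name": "ADULT-M",
  "body_mass_g": 73000.0,
  "organs": {
    "pancreas": 140.0,
    "stomach": 150.0,
    "lungs": 1200.0,
    "blood": 5300.0,
    "liver": 1800.0,
    "kidneys": 310.0,
    "small_intestine": 650.0,
    "urine": 200.0,
    "gallbladder": 10.0,
    "large_intestine": 370.0,
    "heart": 330.0,
    "spleen": 150.0,
    "adrenals": 14.0,
    "thyroid": 20.0,
    "bone": 10500.0,
    "muscle": 29000.0,
    "skin": 3300.0,
    "fat": 14500.0,
    "brain": 1450.0
  }
}
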