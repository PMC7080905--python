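{
  "name": "MOBY-25g",
  "body_mass_g": 25.0,
  "organs": {
    "pancreas": 0.3,
    "stomach": 0.45,
    "lungs": 0.15,
    "blood": 1.8,
    "liver": 1.37,
    "kidneys": 0.33,
    "small_intestine": 1.1,
    "urine": 0.1,
    "gallbladder": 0.02,
    "large_intestine": 0.9,
    "heart": 0.15,
    "spleen": 0.1,
    "adrenals": 0.01,
    "thyroid": 0.005,
    "bone": 2.5,
    "muscle": 9.0,
    "skin": 4.0,
    "fat": 1.5,
    "brain": 0.4
  }
}
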