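{
  "lung": "lungs",
  "colon": "large_intestine",
  "bladder": "urine",
  "urinary_bladder": "urine",
  "bone_surface": "bone",
  "red_marrow": "bone",
  "femur": "bone",
  "stomach_wall": "stomach",
  "small intestine": "small_intestine",
  "large intestine": "large_intestine",
  "gall_bladder": "gallbladder"
}
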