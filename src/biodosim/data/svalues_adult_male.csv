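target,pancreas,stomach,lungs,blood,liver,kidneys,small_intestine,urine,gallbladder,large_intestine,heart,spleen,adrenals,thyroid,bone,muscle,skin,fat,brain,remainder
pancreas,0.996817,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
stomach,9.5576e-05,0.930369,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
lungs,9.5576e-05,9.5576e-05,0.11638,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
blood,9.5576e-05,9.5576e-05,9.5576e-05,0.0264241,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
liver,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0776184,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
kidneys,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.450228,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
small_intestine,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.214774,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
urine,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.697801,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
gallbladder,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,13.9542,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
large_intestine,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.377233,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
heart,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.422947,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
spleen,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.930369,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
adrenals,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.96731,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
thyroid,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,6.97715,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
bone,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0133852,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
muscle,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.00490734,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05
skin,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0423807,9.5576e-05,9.5576e-05,9.5576e-05
fat,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0097191,9.5576e-05,9.5576e-05
brain,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0963308,9.5576e-05
remainder,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,9.5576e-05,0.0387925
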