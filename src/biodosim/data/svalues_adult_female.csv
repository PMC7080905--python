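target,pancreas,stomach,lungs,blood,liver,kidneys,small_intestine,urine,gallbladder,large_intestine,heart,spleen,adrenals,thyroid,bone,muscle,skin,fat,brain,remainder
pancreas,1.16296,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
stomach,0.000116284,0.996838,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
lungs,0.000116284,0.000116284,0.147002,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
blood,0.000116284,0.000116284,0.000116284,0.0341507,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
liver,0.000116284,0.000116284,0.000116284,0.000116284,0.0997884,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
kidneys,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.507538,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
small_intestine,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.232685,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
urine,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.697821,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
gallbladder,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,17.4427,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
large_intestine,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.38773,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
heart,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.55828,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
spleen,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,1.07351,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
adrenals,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,10.734,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
thyroid,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,8.20841,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
bone,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.0180062,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284
muscle,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.00809006,0.000116284,0.000116284,0.000116284,0.000116284
skin,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.0607863,0.000116284,0.000116284,0.000116284
fat,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.00786856,0.000116284,0.000116284
brain,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.107456,0.000116284
remainder,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.000116284,0.0308725
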