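target,pancreas,stomach,lungs,blood,liver,kidneys,small_intestine,urine,gallbladder,large_intestine,heart,spleen,adrenals,thyroid,bone,muscle,skin,fat,brain,remainder
pancreas,465.416,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
stomach,0.279082,310.37,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
lungs,0.279082,0.279082,930.553,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
blood,0.279082,0.279082,0.279082,77.8019,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
liver,0.279082,0.279082,0.279082,0.279082,102.134,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
kidneys,0.279082,0.279082,0.279082,0.279082,0.279082,423.131,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
small_intestine,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,127.135,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
urine,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,1395.69,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
gallbladder,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,6977.33,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
large_intestine,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,155.325,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
heart,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,930.553,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
spleen,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,1395.69,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
adrenals,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,13954.4,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
thyroid,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,27908.5,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082
bone,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,56.0955,0.279082,0.279082,0.279082,0.279082,0.279082
muscle,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,15.7836,0.279082,0.279082,0.279082,0.279082
skin,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,35.1643,0.279082,0.279082,0.279082
fat,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,93.3064,0.279082,0.279082
brain,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,349.132,0.279082
remainder,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,0.279082,171.495
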