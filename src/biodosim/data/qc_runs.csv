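run_id,batch_size_gbq,molar_activity_gbq_umol,radiochemical_purity_pct,ethanol_ppm,acetonitrile_ppm,dmf_ppm,pyridazine_ppm,half_life_min,ph,radiochemical_identity_pct,ascorbic_acid_mg_l,endotoxin_eu_ml,radionuclidic_purity_pct,filter_integrity,appearance,sterility
V-ABT20190417A,12.669,496,99,36743,<LOQ:10,<LOQ:1,<LOQ:1,112,5.5,100,1000,<LOQ:10.0,100,pass,pass,pass
V-ABT20190430A,13.240,251,99,50820,<LOQ:10,<LOQ:1,<LOQ:1,109,5.5,100,1000,<LOQ:10.0,100,pass,pass,pass
V-ABT20190508A,20.890,559,96,45641,<LOQ:10,<LOQ:1,<LOQ:1,110,5.5,100,1000,<LOQ:10.0,100,pass,pass,pass
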