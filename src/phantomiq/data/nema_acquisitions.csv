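nuclide,weight,contrast,ratio,sphere_kbq_ml,background_kbq_ml,trues_millions,duration_s
F18,normal,4:1,4.0,18.21,4.51,70.8,357
F18,obese,4:1,4.0,15.55,3.85,45.0,419
F18,normal,8:1,9.7,51.97,5.35,72.4,291
F18,obese,8:1,9.7,43.59,4.48,45.0,347
Ga68,normal,4:1,4.3,18.75,4.40,71.3,395
Ga68,obese,4:1,4.3,14.63,3.43,44.0,506
Ga68,normal,8:1,9.4,40.65,4.32,69.9,393
Ga68,obese,8:1,9.4,31.52,3.35,44.7,507
Cu64,normal,4:1,5.4,27.70,5.12,72.2,1703
Cu64,obese,4:1,5.4,26.18,4.84,45.0,1801
Cu64,normal,8:1,8.1,42.16,5.19,71.6,1659
Cu64,obese,8:1,8.1,40.04,4.93,44.6,1747
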