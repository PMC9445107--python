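nuclide,contrast,weight,fwhm_mean_mm,fwhm_sd_mm
F18,4:1,normal,4.55,0.18
F18,4:1,obese,4.83,0.32
F18,8:1,normal,4.10,0.21
F18,8:1,obese,4.21,0.24
Ga68,4:1,normal,5.35,0.19
Ga68,4:1,obese,5.35,0.33
Ga68,8:1,normal,4.83,0.16
Ga68,8:1,obese,4.87,0.24
Cu64,4:1,normal,4.35,0.20
Cu64,4:1,obese,4.55,0.19
Cu64,8:1,normal,4.17,0.30
Cu64,8:1,obese,4.30,0.20
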