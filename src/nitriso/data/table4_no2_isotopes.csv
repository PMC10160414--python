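sample,year,fluid_type,no2_um,no2_sd_um,d15n_no2_permil,d15n_no2_sd_permil,d18o_no2_permil,d18o_no2_sd_permil
NSHQ10,2016,gabbro,30.3,1.6,-17.9,1.3,5.2,1.7
NSHQ4,2017,CaOH,4.8,0.8,-4.4,1.0,21.1,3.1
WAB56,2015,CaOH,3.8,0.4,7.8,2.3,22.5,3.3
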