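sample,fluid_type,n2o_nm
BA1A_100_400m,CaOH,5.05
BA1A_55_66m,MgHCO3,177
CM2A,CaOH,5.13
NSHQ14,CaOH,8.70
WAB103,gabbro,24.5
WAB104,MgHCO3,20.3
WAB105,MgHCO3,16.7
WAB188,gabbro,12.6
WAB55,CaOH,18.7
WAB71,CaOH,14.7
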