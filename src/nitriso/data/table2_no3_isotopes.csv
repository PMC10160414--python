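sample,year,fluid_type,no3_um,no3_sd_um,d15n_no3_permil,d15n_no3_sd_permil,d18o_no3_permil,d18o_no3_sd_permil
BA1A_100_400m,2018,CaOH,7.8,0.1,25.2,0.09,34.6,0.5
BA1A_55_66m,2018,MgHCO3,80.7,3.2,6.1,0.06,26.8,0.3
NSHQ10,2016,MgHCO3,66.6,1.1,20.1,0.05,24.3,0.3
NSHQ14,2015,CaOH,1,0.1,15.9,0.09,20.6,0.7
NSHQ14,2018,CaOH,3,0.1,5.6,0.06,12.7,0.5
NSHQ14_18m,2017,CaOH,25.8,1.4,10.6,0.24,9.5,0.3
NSHQ21,2015,gabbro,233,2.5,9.0,0.07,14.9,0.2
NSHQ3B,2015,MgHCO3,102.5,1.1,2.8,0.05,21.7,0.2
NSHQ4,2017,CaOH,8.6,0.5,4.0,0.2,19.5,0.3
rainwater,2017,rainwater,252.2,9.0,-2.2,0.2,55.6,0.3
WAB103,2015,gabbro,367.9,4,8.9,0.06,16.7,0.2
WAB103,2016,gabbro,169.9,2.1,11.8,0.04,18.9,0.2
WAB103,2018,gabbro,292.5,4.9,10.5,0.06,18.1,0.3
WAB104,2016,MgHCO3,138.6,2,1.4,0.03,22.9,0.2
WAB104,2017,MgHCO3,118.6,5.9,2.3,0.2,22.9,0.3
WAB104,2018,MgHCO3,137.5,3.4,1.1,0.06,23.5,0.3
WAB105,2016,MgHCO3,131.4,1.5,2,0.03,23.6,0.2
WAB105,2017,MgHCO3,137.8,4.9,2.5,0.1,21.8,0.6
WAB105,2018,MgHCO3,137.3,3.1,2.2,0.06,22,0.3
WAB188,2015,gabbro,90.7,1,5.5,0.05,22.5,0.2
WAB188,2016,gabbro,147.3,1.7,3.3,0.03,21.8,0.2
WAB188,2017,gabbro,135.9,6.2,5.5,0.04,22.5,0.2
WAB188,2018,gabbro,99.9,3.1,3.2,0.06,21.3,0.3
WAB55,2015,MgHCO3,140,1.5,7.4,0.07,21.1,0.2
WAB55,2016,MgHCO3,142.3,1.7,7.5,0.03,20.8,0.2
WAB55,2017,MgHCO3,145.9,0.9,8.8,0.05,20.9,0.2
WAB55,2018,CaOH,143.5,2.9,7.8,0.06,20.5,0.3
WAB56,2015,CaOH,16.7,0.3,20.7,0.09,30.7,0.2
WAB56,2017,CaOH,14.4,0.8,9.94,0.23,22.8,0.3
WAB71,2017,CaOH,9.5,0.5,13.2,0.26,0.9,0.3
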