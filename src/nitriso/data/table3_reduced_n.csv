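sample,fluid_type,year,nred_um,nred_sd_um,nh3_um,nh3_sd_um,d15n_nred_permil,d15n_nred_sd_permil
BA1A_100_400m,CaOH,2018,80.2,7.6,77.1,10.0,-12.9,1.5
BA1A_55_66m,MgHCO3,2018,32.0,12.3,26.7,0.5,-16.7,6.5
CM2A,CaOH,2018,99.1,8.8,106.2,5.9,6.9,0.9
NSHQ14,CaOH,2018,28.3,2.4,13.4,2.4,4.6,0.5
NSHQ14_18m,CaOH,2017,20.4,1.2,12.7,0.4,5.0,0.6
NSHQ14_50m,CaOH,2017,23.0,0.4,14.2,0.3,9.6,0.2
NSHQ14_85m,CaOH,2017,18.1,0.3,13.0,0.3,4.3,0.2
NSHQ4,CaOH,2017,50.7,1.2,55.5,5.0,0.9,0.1
WAB188,gabbro,2018,41.8,14.5,3.7,1.0,2.4,1.4
WAB56,CaOH,2017,141.6,2.4,,,3.4,0.1
WAB71,CaOH,2017,109.6,2.0,100.3,1.9,11.2,0.3
WAB71,CaOH,2018,105.6,11.1,114.4,3.1,13.6,2.0
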