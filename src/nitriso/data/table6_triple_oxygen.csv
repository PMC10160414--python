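sample,year,d18o_no3_permil,d18o_no3_sd_permil,d17o_no3_permil,d17o_no3_sd_permil,cap_delta17o_permil,cap_delta17o_sd_permil,f_atm,f_atm_conservative
rainwater,2017,53.7,1.8,44.7,3.6,16.8,2.7,1,0.47
WAB104,2018,19.6,1.0,17.1,0.7,6.9,1.2,0.41,0.19
BA1A_100_400m,2018,32.8,,21.3,,4.3,,0.25,0.12
BA1A_55_66m,2018,26.4,,20.7,,6.9,,0.41,0.19
NSHQ14,2018,19.3,,13.1,,3.1,,0.18,0.09
WAB104,2017,23.2,,17.7,,5.7,,0.34,0.16
WAB105,2018,22.5,,18.4,,6.7,,0.40,0.19
WAB188,2018,22.3,,16.1,,4.5,,0.27,0.13
WAB55,2018,20.89,,15.0,,4.09,,0.24,0.11
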