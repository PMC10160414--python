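borehole,depth_m,n_ppm,d15n_bulk_permil
BA1B,280,11.3,4.4
BA3A,280,13.9,3.54
BA4A,280,11.3,6.66
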