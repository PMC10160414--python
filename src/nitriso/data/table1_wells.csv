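well,depth_mbgl,casing_mbct,screened_interval_mbct,depth_to_water_mbct,utm_easting,utm_northing,elevation_mabsl,lithology
BA1A,400.0,22.0,open below casing,13.47,674492,2531354,583,peridotite
CM2A,400.0,23.7,open below casing,13.4,636988,2534284,713,gabbro
NSHQ04,304.0,5.8,open below casing,4.7,670971,2531699,543,peridotite
NSHQ14,304.0,5.8,open below casing,9.2,675495,2529716,526,peridotite
WAB103,101.0,101.0,90-98,15,648577,2530362,632,gabbro
WAB104,120.4,120.4,101-104,40,643099,2541124,842,peridotite
WAB105,120.5,120.5,110-117,16.5,644678,2536524,738,peridotite
WAB188,78.0,78.0,35-51,9.5,671123,2529798,514,gabbro
WAB55,102.0,102.0,8-97,7.5,634777,2506101,531,peridotite
WAB71,136.5,136.5,128-131,8.3,670322,2533981,608,peridotite
NSHQ3B,472.0,185.0,91-180,,645068,2536069,688,alluvium
NSHQ10,304.0,5.8,open below casing,14.3,645706,2502793,453,peridotite
NSHQ21,233.0,5.4,open below casing,3.33,633569,2509105,514,gabbro
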