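department,semester,temp_mean,temp_max,temp_min,insolation,daylength,rainfall,days_rain
Cesar,1st,20.4,27.7,14.9,71475,2142,680,58
Cesar,2nd,21.8,28.0,17.2,78602,2285,1852,100
Cesar,3rd,22.9,27.5,17.2,71463,2142,656,46
Cesar,4th,21.3,28.0,16.5,78614,2285,1171,77
Cesar,Mean,21.6,27.8,16.5,75039,2214,1090,70
Caldas,1st,20.9,28.1,16.7,74647,2169,1501,101
Caldas,2nd,21.2,28.6,17.0,77194,2256,1793,118
Caldas,3rd,20.9,28.1,16.9,74643,2169,1514,104
Caldas,4th,21.2,28.6,16.9,77198,2256,1273,107
Caldas,Mean,21.1,28.4,16.9,75921,2213,1520,108
Quindio,1st,21.7,29.1,17.2,74947,2172,1359,88
Quindio,2nd,22.2,29.8,17.6,77008,2253,952,73
Quindio,3rd,21.7,29.5,17.4,74944,2172,1707,92
Quindio,4th,22.0,29.7,17.5,77011,2253,1040,75
Quindio,Mean,21.9,29.5,17.4,75978,2213,1265,82
Cauca,1st,19.3,24.9,15.4,75930,2182,1420,107
Cauca,2nd,19.0,26.8,13.7,76309,2242,748,65
Cauca,3rd,18.9,26.3,15.1,75930,2182,1529,110
Cauca,4th,19.1,27.1,13.8,76309,2242,601,71
Cauca,Mean,19.1,26.3,14.5,76120,2212,1075,88
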