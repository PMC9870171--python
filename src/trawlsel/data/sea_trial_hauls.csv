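haul_id,treatment,length_cm,n_codend,n_cover,q_codend,q_cover,duration_min,depth_m,speed_kt,date
1,shaking,23,390,337,0.0845,0.2643,18,129,2.4,2019-07-16
2,shaking,23,199,371,0.2701,0.8690,10,129,2.5,2019-07-16
3,shaking,23,163,363,0.0838,0.1974,6,132,2.5,2019-07-16
4,shaking,23,285,369,0.3432,0.6452,6,140,2.4,2019-07-16
5,T90,23,287,81,0.6435,1,5,179,2.4,2019-07-17
6,T90,23,133,156,0.2036,1,9,180,2.3,2019-07-17
7,T90,23,349,319,0.0957,0.3734,10,178,2.6,2019-07-17
8,T90,23,358,358,0.0567,0.1533,9,177,2.5,2019-07-17
9,T90,23,234,337,0.0871,1,7,178,2.5,2019-07-17
10,T90,23,138,65,0.2108,1,7,176,2.5,2019-07-17
11,T90,23,384,384,0.1115,0.6540,7,172,2.4,2019-07-18
12,T90,23,362,407,0.0975,0.4815,8,172,2.4,2019-07-18
13,T90,23,334,339,0.0839,0.2018,6,178,2.5,2019-07-18
14,T90,23,364,328,0.0707,0.3385,5,177,2.6,2019-07-18
15,T90,23,335,305,0.0560,0.1860,4,172,2.4,2019-07-18
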