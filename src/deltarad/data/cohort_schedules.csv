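patient_id,response,total_bed_gy,bed_per_fraction_gy,bed20_pair,bed40_pair
1,RS,72,14.4,Fx1-Fx3,Fx1-Fx4
2,NR,59.5,11.9,Fx1-Fx3,Fx1-Fx5
3,NR,72,14.4,Fx1-Fx3,Fx1-Fx4
4,NR,100,20,Fx1-Fx2,Fx1-Fx3
5,NR,59.5,11.9,Fx1-Fx3,Fx1-Fx5
6,RS,54.8,11.0,Fx1-Fx3,Fx1-Fx5
7,RS,72,14.4,Fx1-Fx3,Fx1-Fx4
8,NR,72,14.4,Fx1-Fx3,Fx1-Fx4
9,NR,72,14.4,Fx1-Fx3,Fx1-Fx4
10,RS,59.5,11.9,Fx1-Fx3,Fx1-Fx5
11,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
12,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
13,RS,100,20.0,Fx1-Fx2,Fx1-Fx3
14,RS,132,26.4,Fx1-Fx2,Fx1-Fx3
15,RS,100,20.0,Fx1-Fx2,Fx1-Fx3
16,RS,100,20.0,Fx1-Fx2,Fx1-Fx3
17,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
18,RS,61.5,12.3,Fx1-Fx3,Fx1-Fx5
19,RS,100,20.0,Fx1-Fx2,Fx1-Fx3
20,RS,100,20.0,Fx1-Fx2,Fx1-Fx3
21,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
22,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
23,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
24,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
25,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
26,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
27,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
28,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
29,NR,100,20.0,Fx1-Fx2,Fx1-Fx3
30,NR,72,14.4,Fx1-Fx3,Fx1-Fx4
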