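neuron_id,session_id,rate,auc,category,fov_id,cohort
0,0,4,10.7403105,intermediate,0,
0,1,2.5,10.6617218,intermediate,0,
0,2,3.5,9.59450786,intermediate,0,
1,0,0,8.2067062,rare,0,
1,1,1.5,9.2201221,intermediate,0,
1,2,1.5,8.48971522,intermediate,0,
2,0,0.5,8.52027301,intermediate,0,
2,1,1,9.2878803,intermediate,0,
2,2,3,10.3324527,intermediate,0,
3,0,4,11.657495,intermediate,0,
3,1,4.5,12.2819888,high,0,
3,2,2.5,11.7475529,intermediate,0,
4,0,8.5,13.7011506,high,0,
4,1,6.5,15.3155695,high,0,
4,2,7.5,13.1121375,high,0,
5,0,0.5,9.07720146,intermediate,0,
5,1,0,7.89442451,rare,0,
5,2,0.5,7.97367005,intermediate,0,
6,0,0,6.98090737,rare,0,
6,1,0,7.92406621,rare,0,
6,2,0.5,7.72232698,intermediate,0,
7,0,7.5,14.5101287,high,0,
7,1,6.5,13.6634407,high,0,
7,2,5.5,11.6495806,high,0,
8,0,0,7.94271562,rare,0,
8,1,1,9.66992491,intermediate,0,
8,2,3,10.8430474,intermediate,0,
9,0,1,8.59759695,intermediate,0,
9,1,3.5,12.8853692,intermediate,0,
9,2,5.5,12.8929003,high,0,
10,0,3.5,10.7129767,intermediate,0,
10,1,1,8.49264092,intermediate,0,
10,2,3,10.9783252,intermediate,0,
11,0,5,12.6584536,high,0,
11,1,9,13.7383186,high,0,
11,2,7,15.0795441,high,0,
12,0,2.5,10.1586474,intermediate,0,
12,1,3.5,11.3675649,intermediate,0,
12,2,5,11.4099411,high,0,
13,0,7.5,13.8406522,high,0,
13,1,6,13.7003549,high,0,
13,2,5,13.9760882,high,0,
14,0,2.5,9.50830999,intermediate,0,
14,1,1,8.94107023,intermediate,0,
14,2,0.5,7.64039879,intermediate,0,
15,0,1.5,8.83266219,intermediate,0,
15,1,2,9.25221521,intermediate,0,
15,2,1.5,8.49252738,intermediate,0,
16,0,0.5,8.02276085,intermediate,0,
16,1,1,8.27752937,intermediate,0,
16,2,2,10.0972585,intermediate,0,
17,0,2.5,10.7794437,intermediate,0,
17,1,6,15.5607657,high,0,
17,2,5,12.6986013,high,0,
18,0,2,9.19091397,intermediate,0,
18,1,2,10.2949706,intermediate,0,
18,2,2,10.2853786,intermediate,0,
19,0,3.5,11.3818372,intermediate,0,
19,1,1.5,8.77157461,intermediate,0,
19,2,1,8.67996667,intermediate,0,
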