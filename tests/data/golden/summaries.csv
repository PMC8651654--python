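session,neuron,transients_per_min,auc_per_min,category,is_active,n_events,flags
0,0,4,10.7403105,intermediate,True,8,
0,1,0,8.2067062,rare,False,0,
0,2,0.5,8.52027301,intermediate,True,1,
0,3,4,11.657495,intermediate,True,8,
0,4,8.5,13.7011506,high,True,17,
0,5,0.5,9.07720146,intermediate,True,1,
0,6,0,6.98090737,rare,False,0,
0,7,7.5,14.5101287,high,True,15,
0,8,0,7.94271562,rare,False,0,
0,9,1,8.59759695,intermediate,True,2,
0,10,3.5,10.7129767,intermediate,True,7,
0,11,5,12.6584536,high,True,10,
0,12,2.5,10.1586474,intermediate,True,5,
0,13,7.5,13.8406522,high,True,15,
0,14,2.5,9.50830999,intermediate,True,5,
0,15,1.5,8.83266219,intermediate,True,3,
0,16,0.5,8.02276085,intermediate,True,1,
0,17,2.5,10.7794437,intermediate,True,5,
0,18,2,9.19091397,intermediate,True,4,
0,19,3.5,11.3818372,intermediate,True,7,
1,0,2.5,10.6617218,intermediate,True,5,
1,1,1.5,9.2201221,intermediate,True,3,
1,2,1,9.2878803,intermediate,True,2,
1,3,4.5,12.2819888,high,True,9,
1,4,6.5,15.3155695,high,True,13,
1,5,0,7.89442451,rare,False,0,
1,6,0,7.92406621,rare,False,0,
1,7,6.5,13.6634407,high,True,13,
1,8,1,9.66992491,intermediate,True,2,
1,9,3.5,12.8853692,intermediate,True,7,
1,10,1,8.49264092,intermediate,True,2,
1,11,9,13.7383186,high,True,18,
1,12,3.5,11.3675649,intermediate,True,7,
1,13,6,13.7003549,high,True,12,
1,14,1,8.94107023,intermediate,True,2,
1,15,2,9.25221521,intermediate,True,4,
1,16,1,8.27752937,intermediate,True,2,
1,17,6,15.5607657,high,True,12,
1,18,2,10.2949706,intermediate,True,4,
1,19,1.5,8.77157461,intermediate,True,3,
2,0,3.5,9.59450786,intermediate,True,7,
2,1,1.5,8.48971522,intermediate,True,3,
2,2,3,10.3324527,intermediate,True,6,
2,3,2.5,11.7475529,intermediate,True,5,
2,4,7.5,13.1121375,high,True,15,
2,5,0.5,7.97367005,intermediate,True,1,
2,6,0.5,7.72232698,intermediate,True,1,
2,7,5.5,11.6495806,high,True,11,
2,8,3,10.8430474,intermediate,True,6,
2,9,5.5,12.8929003,high,True,11,
2,10,3,10.9783252,intermediate,True,6,
2,11,7,15.0795441,high,True,14,
2,12,5,11.4099411,high,True,10,
2,13,5,13.9760882,high,True,10,
2,14,0.5,7.64039879,intermediate,True,1,
2,15,1.5,8.49252738,intermediate,True,3,
2,16,2,10.0972585,intermediate,True,4,
2,17,5,12.6986013,high,True,10,
2,18,2,10.2853786,intermediate,True,4,
2,19,1,8.67996667,intermediate,True,2,
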