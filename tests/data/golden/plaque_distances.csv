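session,neuron,distance_um,class
0,0,6.88416586,close
0,1,12.3087144,close
0,2,3.45919319,close
0,3,13.2969964,close
0,4,8.39560373,close
0,5,10.8876261,close
0,6,15.8867911,close
0,7,14.5119482,close
0,8,15.6203614,close
0,9,9.77232432,close
0,10,6.52846356,close
0,11,10.1635813,close
0,12,30.8286776,close
0,13,15.7145116,close
0,14,0.25506912,close
0,15,7.55298324,close
0,16,16.0468928,close
0,17,12.2705094,close
0,18,11.6457249,close
0,19,2.28684968,close
1,0,5.44054313,close
1,1,10.8180942,close
1,2,2.11979921,close
1,3,11.550206,close
1,4,6.97078981,close
1,5,9.31945827,close
1,6,14.4567012,close
1,7,12.9541768,close
1,8,14.0851306,close
1,9,8.16469,close
1,10,5.07777789,close
1,11,8.77501066,close
1,12,29.3846519,close
1,13,14.1392394,close
1,14,0.25506912,close
1,15,6.12493063,close
1,16,14.5902932,close
1,17,10.8523719,close
1,18,10.0422685,close
1,19,0.727157795,close
2,0,3.87535213,close
2,1,9.25705448,close
2,2,0.642625186,close
2,3,10.0514554,close
2,4,5.30680829,close
2,5,7.79224753,close
2,6,13.0539783,close
2,7,11.5262656,close
2,8,12.5624603,close
2,9,6.68497526,close
2,10,3.56252697,close
2,11,7.40450348,close
2,12,27.8594845,close
2,13,12.6841689,close
2,14,0.25506912,close
2,15,4.56629047,close
2,16,13.0682112,close
2,17,9.3170863,close
2,18,8.57749673,close
2,19,0.410552246,close
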