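session,mean_r,null_mean_r,n_pairs,n_excluded_pairs,mean_r_whisk,mean_r_stationary
0,0.0551232486,0.000268480826,190,19,0.0112744957,0.0651117629
1,0.000658548245,-0.000757973995,190,0,,-0.00207474638
2,0.0740726025,-0.00104086135,190,0,0.2093753,0.0585925577
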