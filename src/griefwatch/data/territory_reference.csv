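territory_id,n_tweets,daily_average,n_spikes,n_matches
5,970,0.53,10,9
6,177,0.10,2,2
7,1157,0.63,12,11
8,2699,1.48,14,7
10,437,0.24,4,2
15,994,0.55,6,6
16,796,0.44,10,7
17,334,0.18,6,4
24,1083,0.59,11,10
26,370,0.20,3,3
27,162,0.09,2,2
36,182,0.10,4,4
37,1015,0.56,7,6
43,1157,0.06,11,9
45,229,0.13,4,4
49,151,0.08,2,2
54,336,0.18,4,1
58,237,0.13,2,2
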