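r_cm,g_l
0.15,1.02064
0.2,1.02996
0.25,1.03404
0.3,1.03725
0.4,1.03811
0.5,1.03593
0.6,1.03194
0.8,1.01669
1.0,1.00000
1.25,0.96949
1.5,0.93364
1.75,0.89406
2.0,0.85821
2.5,0.77293
3.0,0.68845
3.5,0.60471
4.0,0.52291
5.0,0.35467
6.0,0.21174
8.0,0.08789
10.0,0.03684
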