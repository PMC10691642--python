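theta_deg,0.5,10.0
0,0.3600,0.3600
10,0.5500,0.5500
20,0.7300,0.7300
30,0.8500,0.8500
40,0.9200,0.9200
50,0.9600,0.9600
60,0.9800,0.9800
70,0.9900,0.9900
80,1.0000,1.0000
90,1.0000,1.0000
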