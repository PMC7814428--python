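correction_deg,spoi_20,spoi_10,spoi_0,spoi_-10
0,10.0,10.0,10.0,10.0
5,10.0,10.0,10.0,9.9
10,10.1,10.0,9.9,9.7
15,10.3,10.0,9.7,9.4
20,10.6,10.0,9.4,8.9
25,10.9,10.0,9.1,8.3
30,11.3,10.0,8.7,7.5
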