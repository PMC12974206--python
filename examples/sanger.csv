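position,A,C,G,T
1,1.0,0.0,0.0,0.0
2,1.0,0.0,0.0,0.0
3,1.0,0.0,0.0,0.0
4,1.0,0.0,0.0,0.0
5,1.0,0.0,0.0,0.0
6,0.83,0.0,0.17,0.0
7,1.0,0.0,0.0,0.0
8,1.0,0.0,0.0,0.0
9,0.717,0.0,0.28300000000000003,0.0
10,1.0,0.0,0.0,0.0
11,1.0,0.0,0.0,0.0
12,1.0,0.0,0.0,0.0
13,1.0,0.0,0.0,0.0
14,0.975,0.0,0.025,0.0
15,1.0,0.0,0.0,0.0
16,1.0,0.0,0.0,0.0
17,1.0,0.0,0.0,0.0
18,1.0,0.0,0.0,0.0
19,1.0,0.0,0.0,0.0
20,1.0,0.0,0.0,0.0
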