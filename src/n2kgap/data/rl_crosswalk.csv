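annex_code,rl_code,relation,include
3110,C1.1a,same,1
3120,C1.1b,same,1
3120,C1.6b,close,1
3130,C1.6a,wider,1
3140,C1.2a,same,1
3150,C1.3,same,1
3160,C1.4,same,1
3170,C1.6b,same,1
3170,C1.5a,close,1
3180,C1.7,same,1
3180,C1.2b,low_importance,1
3190,C1.6a,wider,1
31A0,C1.3b,close,1
3210,C2.2,same,1
3220,C2.3,wider,1
3230,F9.1,wider,1
3240,F9.1,same,1
3250,C3.5b,same,1
3260,C2.2,close,1
3270,C3.5a,same,1
3280,C3.5b,narrower,1
3290,C2.5,same,1
32A0,C2.2a,same,1
7110,D1.1,same,1
7120,D1.1,wider,1
7130,D1.2,same,1
7140,D2.3,same,1
7150,D2.3b,same,1
7160,D2.2c,same,1
7160,D4.1,low_importance,1
7210,D5.2,same,1
7220,D4.1a,same,1
7230,D4.1,same,1
7240,D4.2,same,1
7310,D3.2,same,1
7320,D3.1,same,1
9080,G1.4a,same,1
91D0,G1.5,same,1
91E0,G1.2,same,1
91F0,G1.2b,same,1
92A0,G1.3,same,1
92B0,G1.3a,narrower,1
92C0,G1.3b,same,1
92D0,F9.3,close,1
1130,RL-AGG-1130,same,1
1650,RL-AGG-1650,same,1
2190,B1.8,same,1
4010,F4.11,same,1
4020,F4.12,same,1
6410,E3.5,same,1
6430,E5.4,same,1
6440,E3.4,same,1
6450,E3.4a,same,1
6460,E3.1,same,1
6540,E3.3,same,1
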