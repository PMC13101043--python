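rl_code,regions
C1.1a,Atlantic;Boreal;Continental
C1.1b,Atlantic;Boreal
C1.2a,UNSPECIFIED
C1.2b,Continental
C1.3,UNSPECIFIED
C1.3b,Pannonian
C1.4,UNSPECIFIED
C1.5a,Atlantic
C1.6a,UNSPECIFIED
C1.6b,Mediterranean
C1.7,Atlantic
C2.2,UNSPECIFIED
C2.2a,Alpine;Continental;Mediterranean
C2.3,UNSPECIFIED
C2.5,Mediterranean;Pannonian
C3.5a,UNSPECIFIED
C3.5b,Atlantic;Continental;Mediterranean
F9.1,UNSPECIFIED
F9.3,Mediterranean
D1.1,Alpine;Atlantic;Boreal;Continental
D1.2,Atlantic
D2.2c,Boreal;Continental
D2.3,UNSPECIFIED
D2.3b,Atlantic;Boreal;Continental
D3.1,Boreal
D3.2,Alpine;Boreal
D4.1,UNSPECIFIED
D4.1a,UNSPECIFIED
D4.2,Alpine;Boreal
D5.2,UNSPECIFIED
G1.2,UNSPECIFIED
G1.2b,UNSPECIFIED
G1.3,Continental;Mediterranean;Pannonian
G1.3a,Mediterranean
G1.3b,Mediterranean
G1.4a,Boreal
G1.5,Alpine;Atlantic;Boreal;Continental
RL-AGG-1130,Atlantic;Boreal;Continental;Mediterranean
RL-AGG-1650,Boreal;Continental
B1.8,Atlantic;Boreal;Continental
F4.11,Atlantic;Boreal;Continental
F4.12,Atlantic
E3.1,Mediterranean
E3.3,Continental;Mediterranean
E3.4,Continental;Pannonian
E3.4a,Boreal
E3.5,UNSPECIFIED
E5.4,UNSPECIFIED
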