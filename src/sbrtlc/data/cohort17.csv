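id,sex,age,stage
1,F,71,T1
2,M,71,T1
3,M,68,T1
4,F,72,T1
5,M,64,T1
6,M,68,T1
7,M,70,T1
8,M,62,T1
9,F,63,T1
10,F,70,T1
11,F,55,T1
12,M,62,T1
13,F,59,T1
14,F,76,T1
15,M,72,T2
16,F,56,T2
17,M,51,T2
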