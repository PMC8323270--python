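index,name,region
1,m1,reference
2,F7,frontal
3,T3,temporal
4,T5,temporal
5,Fp1,frontal
6,F3,frontal
7,C3,central
8,P3,parietal
9,O1,occipital
10,Afz,frontal
11,Fz,frontal
12,Cz,central
13,Pz,parietal
14,Fp2,frontal
15,F4,frontal
16,C4,central
17,P4,parietal
18,O2,occipital
19,m2,reference
20,F8,frontal
21,T4,temporal
22,T6,temporal
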