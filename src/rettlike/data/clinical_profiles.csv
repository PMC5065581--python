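proband,age_years,onset_of_signs,microcephaly,sitting_alone,ambulation,respiratory_function,epilepsy,hand_use,stereotypies,language
3,14,3,1,2,4,1,1,3,2,2
8,7,3,1,1,4,1,2,1,3,2
10,16,3,1,1,2,1,2,1,1,2
12,11,3,1,1,4,1,0,2,2,1
13,10,3,1,2,4,1,1,2,3,2
14,2,3,1,1,2,0,1,3,2,2
19,2,3,1,1,4,0,0,3,2,2
20,24,3,1,1,1,1,0,2,2,1
21,5,3,1,3,4,0,1,2,1,2
22,17,3,0,1,2,0,1,2,3,2
23,0.125,3,1,1,2,1,0,3,3,2
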