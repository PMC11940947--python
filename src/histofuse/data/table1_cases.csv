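case_id,sex,age_at_diagnosis,survival_months,localization,included,duplicate_of
1,F,62,16,Right occipital,true,
2,M,55,14,"Left occipital, parietal",true,
3,F,46,10,Left frontal,true,
4,M,70,4,Right frontal,true,
5,F,54,95,Left parietal,false,
6,M,33,15,Right frontal,false,
7,F,57,4,Right frontotemporal,true,
8,F,48,27,"Right frontal, occipital, parietal, temporal",false,
9,M,65,14,Right frontal,true,
10,M,69,16,Right frontal,true,
11,M,51,23,Left parietal,false,
12,F,55,12,Left frontal,true,
13,F,85,4,Left temporal,false,
14,F,72,13,Right temporal,false,
15,M,77,20,Right parietal,true,
16,M,33,15,Right frontal,false,6
17,F,51,,Right frontal,false,
18,M,50,16,Left temporal,false,
19,F,60,20,Right temporal,false,
20,F,75,27,Right frontal,false,
21,M,65,10,Left temporal,true,
22,M,33,8,Right frontal,false,
23,F,60,21,Left temporal,false,
24,M,68,10,Left frontal,false,
25,F,59,38,Right occipital,false,
26,F,79,12,Right parietal,true,
27,M,73,17,Right frontal,false,
28,M,50,20,Right parietal,true,
29,M,66,12,Right parietal,true,
30,M,50,15,Right temporal,true,
31,M,78,5,Right frontal,false,
32,F,60,15,Right occipital,false,
33,M,75,16,Right occipital,true,
34,F,62,13,"Right occipital, parietal",false,
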