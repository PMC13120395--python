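cat_id,exposure,age,sex,smoker_owners,cigarettes_per_day
1,exposed,1,M,1,6
2,exposed,2,M,2,10
3,exposed,1,F,1,10
4,exposed,5,M,1,10
5,exposed,1,M,1,7
6,exposed,1,F,1,10
7,exposed,2,M,1,10
8,exposed,5,M,1,5
9,exposed,1,M,1,10
10,exposed,5,M,1,10
11,exposed,1,M,1,5
12,exposed,5,M,1,7
13,exposed,5,F,2,9
14,exposed,5,M,2,11
15,exposed,5,F,1,5
16,exposed,1,M,1,7
17,exposed,5,M,1,6
18,exposed,1,F,2,9
19,exposed,1,F,1,4
20,exposed,1,F,1,8
21,non_exposed,5,F,0,0
22,non_exposed,5,M,0,0
23,non_exposed,4,F,0,0
24,non_exposed,1,F,0,0
25,non_exposed,5,F,0,0
26,non_exposed,5,M,0,0
27,non_exposed,5,F,0,0
28,non_exposed,1,M,0,0
29,non_exposed,4,M,0,0
30,non_exposed,2,F,0,0
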