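upsit_score,ss_equivalent
0,0.0
1,0.5
2,1.0
3,1.0
4,1.5
5,2.0
6,2.5
7,3.0
8,3.0
9,3.5
10,4.0
11,4.5
12,5.0
13,5.0
14,5.5
15,6.0
16,6.5
17,7.0
18,7.0
19,7.5
20,8.0
21,8.5
22,9.0
23,9.0
24,9.5
25,10.0
26,10.5
27,11.0
28,11.0
29,11.5
30,12.0
31,12.5
32,13.0
33,13.0
34,13.5
35,14.0
36,14.5
37,15.0
38,15.0
39,15.5
40,16.0
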