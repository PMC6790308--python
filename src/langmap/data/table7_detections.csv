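patient,modality,MTG,ANG,TP,IFG,SMA_preSMA,dACC,AIFO
1,task,Bi,Bi,Bi,Bi,Bi,Bi,Bi
1,rest,Bi,Bi,No,Bi,No,Bi,No
2,task,Left,Left,No,Left,No,No,No
2,rest,Left,Left,Left,Left,No,No,No
3,task,No,No,No,No,No,No,No
3,rest,Left,Left,No,Left,Bi,No,No
4,task,No,Bi,No,No,No,No,No
4,rest,Left,Bi,No,Left,Bi,No,No
5,task,Bi,Left,No,Left,Bi,Bi,Bi
5,rest,Bi,Bi,Left,Bi,No,Bi,Left
6,task,Bi,Left,No,Bi,Bi,No,Bi
6,rest,Bi,Left,No,Bi,Left,Left,No
7,task,Right,No,No,No,No,Bi,No
7,rest,Bi,Left,No,Left,No,No,No
8,task,Left,Left,No,Left,No,Bi,Right
8,rest,Left,Left,No,Bi,No,No,Right
9,task,No,Bi,Left,No,No,No,No
9,rest,Bi,Bi,Right,Bi,No,No,No
10,task,Bi,Bi,Bi,Left,No,Bi,Left
10,rest,Bi,No,No,Bi,No,No,Right
11,task,Bi,Left,No,Bi,Bi,No,Bi
11,rest,Bi,Right,Right,Bi,No,Bi,No
12,task,Bi,Left,No,Bi,Bi,Bi,Right
12,rest,Bi,Bi,No,Bi,No,No,No
13,task,Left,Bi,No,Left,No,Bi,Bi
13,rest,Bi,Bi,No,Bi,No,No,Left
14,task,Bi,Bi,Bi,Bi,Bi,Bi,Bi
14,rest,Bi,Bi,Right,Bi,No,No,No
15,task,No,No,No,No,No,No,No
15,rest,Bi,Bi,Right,Bi,No,No,No
16,task,No,No,No,No,No,No,No
16,rest,Bi,Right,Right,Bi,No,Left,No
17,task,Bi,Left,No,Left,Bi,Bi,Bi
17,rest,Bi,Right,No,Bi,No,Left,No
18,task,No,Left,No,No,No,No,No
18,rest,Bi,Left,No,Bi,No,Left,No
19,task,Right,Bi,No,Bi,No,Right,Right
19,rest,Left,Left,No,Bi,No,No,Right
20,task,Bi,Right,Bi,Bi,Bi,Bi,Bi
20,rest,Bi,Right,No,Bi,No,Right,No
21,task,Bi,Bi,No,Bi,Bi,Bi,Bi
21,rest,Left,Bi,No,Bi,No,No,No
22,task,Left,Left,No,No,No,No,No
22,rest,Bi,Bi,No,Bi,No,No,No
23,task,No,No,No,No,No,No,No
23,rest,Bi,Bi,No,Bi,No,No,No
24,task,No,No,No,No,Left,No,No
24,rest,Bi,Bi,Left,Bi,No,No,No
25,task,Bi,Bi,Left,Bi,Bi,Bi,Bi
25,rest,Bi,Bi,No,Right,Right,No,No
26,task,Left,No,Left,Bi,No,No,Bi
26,rest,Left,Right,Bi,Bi,No,Left,No
27,task,No,No,No,No,No,Bi,No
27,rest,Bi,Left,Left,Left,No,No,No
28,task,No,No,No,No,No,No,No
28,rest,Bi,Left,No,Bi,No,Left,No
29,task,No,Bi,No,No,No,No,No
29,rest,Bi,Bi,Left,Bi,No,No,No
30,task,Right,No,No,No,No,No,No
30,rest,Bi,No,Right,Bi,No,No,No
31,task,Bi,Bi,No,Left,Bi,No,Bi
31,rest,Bi,Left,No,Bi,No,No,No
32,task,Right,No,No,No,No,Bi,No
32,rest,Bi,Bi,Right,Bi,No,No,No
33,task,No,No,No,No,No,No,No
33,rest,Bi,Bi,Right,Bi,No,No,No
34,task,Bi,Bi,No,Bi,Bi,Bi,Bi
34,rest,Right,Right,Right,Bi,No,No,No
35,task,Bi,Left,No,Right,No,Bi,Right
35,rest,Bi,Left,No,Bi,No,No,No
36,task,Bi,Bi,Left,Bi,Bi,Left,Bi
36,rest,Bi,Bi,Left,Bi,No,No,No
37,task,Bi,Bi,No,Left,Left,No,Left
37,rest,Bi,Left,No,Bi,No,No,No
38,task,No,No,No,No,No,No,No
38,rest,Bi,Left,No,Bi,No,No,No
39,task,Right,Bi,No,Bi,Bi,No,Bi
39,rest,Bi,Right,Right,Left,No,Bi,No
40,task,Left,Bi,No,Bi,Bi,No,No
40,rest,Bi,Left,Left,Bi,No,Bi,No
41,task,Left,Bi,No,Bi,No,No,No
41,rest,Bi,Left,Right,Bi,No,No,No
42,task,Bi,Bi,No,Bi,Bi,No,Bi
42,rest,Bi,Bi,No,Right,Left,No,No
43,task,Left,Left,Left,Bi,No,Bi,Left
43,rest,Left,Left,Right,Left,No,No,Right
44,task,Left,Bi,Bi,Left,Bi,No,Bi
44,rest,Bi,Left,Left,Left,Left,No,Left
45,task,Left,Bi,Bi,Bi,Bi,No,Bi
45,rest,Bi,Bi,Bi,Left,Left,No,Left
46,task,No,Bi,Bi,Bi,Bi,No,Bi
46,rest,Bi,Bi,Right,Bi,Right,Left,No
47,task,No,Bi,Bi,Bi,Bi,Bi,Bi
47,rest,Left,Bi,Bi,Left,Bi,Bi,Right
48,task,No,Bi,Bi,Bi,Bi,No,Right
48,rest,Bi,Bi,Bi,Left,No,Bi,No
49,task,Left,Bi,Bi,Bi,Bi,Bi,Bi
49,rest,Left,Left,No,Left,Bi,No,Left
50,task,Left,Bi,Bi,Bi,Bi,Left,Bi
50,rest,Bi,Bi,Bi,Bi,Left,No,No
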