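patient,site_label,region,side,rest_only
3,Left MTG,MTG,L,1
4,Left ANG,ANG,L,0
4,Left MTG,MTG,L,1
5,Left IFG,IFG,L,0
6,Left IFG,IFG,L,0
7,Left IFG,IFG,L,1
8,Left IFG,IFG,L,0
11,Left MFG,MFG,L,0
12,Left IFG,IFG,L,0
13,Left IFG,IFG,L,0
15,Left IFG,IFG,L,1
16,Left IFG,IFG,L,1
17,Left IFG,IFG,L,0
18,Left ANG,ANG,L,0
19,Left IFG,IFG,L,0
20,Left IFG,IFG,L,0
21,Left ANG,ANG,L,0
22,Left MTG,MTG,L,0
25,Right IFG,IFG,R,1
27,Left SMA/pre-SMA,SMA_preSMA,L,0
28,Left superior frontal gyrus,SFG,L,1
30,Left IFG,IFG,L,1
31,Left MTG,MTG,L,0
32,Left MTG,MTG,L,1
36,Left ANG,ANG,L,0
37,Left MTG,MTG,L,0
40,Left IFG,IFG,L,0
42,Left superior frontal junction,SFJ,L,1
44,Left middle temporal gyrus,MTG,L,0
45,Posterior part of left middle frontal gyrus,MFG,L,0
46,Left middle temporal gyrus,MTG,L,1
48,Middle part of left inferior frontal gyrus,IFG,L,0
0,unspecified,unspecified,L,0
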