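patient,edinburgh,tia,rest
1,43,-26,-60
2,8,61,84
3,82,66,70
4,100,3,70
5,82,-41,-57
6,20,3,75
7,-67,-55,82
8,80,22,6
9,82,14,59
10,-80,-28,65
11,100,72,73
12,69,-48,81
13,82,-48,62
14,100,-17,44
15,100,-19,55
16,80,-38,77
17,51,59,49
18,82,25,-30
19,80,-66,91
20,82,32,-82
21,50,-57,81
22,18,9,72
23,5,22,73
24,-100,56,-70
25,-60,10,55
26,100,-20,66
27,82,-14,67
28,80,-9,63
29,80,7,68
30,50,36,86
31,80,-45,86
32,80,26,-81
33,80,-24,78
34,83,21,74
35,60,62,67
36,57,23,-72
37,66,-55,92
38,30,38,42
39,100,13,25
40,100,32,76
41,33,-42,-10
42,-60,1,-87
43,50,46,72
44,25,-12,-48
45,80,12,18
46,100,-55,-4
47,67,24,-12
48,67,-27,-87
49,-60,56,96
50,100,49,-5
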