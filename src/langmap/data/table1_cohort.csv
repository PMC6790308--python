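patient,sex,age,lesion_side,lesion_location,histology,language_disturbance,anxiety,success
1,F,54,L,Precentral gyrus,GB,Mild,7.7,4.9
2,M,18,L,Superior frontal gyrus,DNET,No,2.7,8.9
3,F,59,L,Superior temporal gyrus,Lung adenocarcinoma metastasis,Mild,8.2,7.2
4,F,47,L,Fusiform gyrus,XA II,No,1.5,7.9
5,F,51,L,Inferior frontal gyrus,GB,No,1.3,8.2
6,M,64,L,Precentral gyrus,GB,No,1.6,4.6
7,M,35,L,Precentral gyrus,AA III,Mild,0.3,5.2
8,F,68,L,Hippocampus,GB,No,10,5.1
9,M,63,L,Middle temporal gyrus,GB,No,1.9,7.7
10,M,34,R,Superior frontal gyrus,OA III,No,4.8,5.8
11,F,29,L,Superior frontal gyrus,OA II,No,3.2,8.2
12,F,53,L,Fronto-insular,OA III,No,0.0,5.9
13,M,36,L,Middle frontal gyrus,OA II,No,6.1,4.5
14,M,48,L,Precentral gyrus,OA III,No,6.5,8.0
15,F,60,L,SMA,GB,No,0.0,5.2
16,F,42,L,Superior frontal gyrus,OD III,No,2.4,8.0
17,M,22,L,Temporo-insular,GG,No,7.6,7.6
18,M,67,L,Angular gyrus,GB,Mild,5.7,10
19,F,58,L,Superior parietal lobule,PA,No,,
20,M,49,L,Precentral gyrus,OA III,Mild,2.6,6.9
21,M,42,L,Inferior frontal gyrus,GB,No,0.8,6.8
22,M,30,L,Inferior temporal gyrus,OA III,No,1.8,7.0
23,M,65,L,Angular gyrus,Lung adenocarcinoma metastasis,No,3.4,4.4
24,M,52,R,Superior frontal gyrus,GS,No,2.2,9.6
25,F,69,R,Fronto-temporo-insular,GB,Mild,5.3,5.2
26,F,39,L,Lingual gyrus,AB,No,3.0,6.2
27,M,75,R,Middle frontal gyrus,OA III,No,5.6,3.9
28,M,58,L,Inferior frontal gyrus,Radionecrosis,No,0.8,6.6
29,M,55,L,Parahippocampal gyrus,GB,Mild,0.0,7.1
30,F,66,L,Superior frontal gyrus,GB,No,3.8,3.8
31,M,64,L,Lingual gyrus,GB,No,0.0,6.3
32,M,57,L,Parahippocampal gyrus,Cavernoma,No,4.9,6.9
33,M,47,L,Superior frontal gyrus,OD III,No,4.9,6.9
34,M,50,L,Thalamic,GB,No,0.3,7.6
35,M,52,L,Fronto-insular,AA III,No,3.1,6.6
36,M,62,L,Parietal,GB,No,2.5,2.5
37,M,62,L,Angular gyrus,GB,Mild,1.3,4.3
38,M,50,L,Fusiform gyrus,GB,No,0.0,8.5
39,F,45,L,Inferior temporal gyrus,PA,No,0.0,8.1
40,F,51,L,Middle frontal gyrus,GB,Mild,4.3,4.4
41,M,24,L,Superior frontal gyrus,OA II,No,3.5,7.2
42,M,41,L,Precentral gyrus,OA II,No,5.0,5.3
43,M,39,L,Operculum,GB,Severe,6.5,4.6
44,M,47,L,Middle temporal gyrus,Cavernoma,No,6.0,5.0
45,M,40,L,Supramarginal gyrus,Cavernoma,No,5.0,8.3
46,F,35,L,Angular gyrus,Arteriovenous malformation,No,2.0,7.1
47,M,46,R,Angular gyrus,GB,No,5.3,3.2
48,M,56,L,Middle frontal gyrus,GB,No,4.2,8.0
49,M,69,R,Occipital,AA III,No,3.0,6.0
50,M,34,L,Supramarginal gyrus,GB,Mild,5.3,6.2
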