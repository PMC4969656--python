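case,age_range_y,weight_kg,dosage_MBq,dosage_per_weight_MBq_kg,tumor_location,pathology,tnm,stage
1,80-89,43.3,142,3.3,L S3,Ade,pT1aN0M0,IA
2,70-79,56.5,166,2.9,R S6,SCC,cT3N2M0,IIIA
3,80-89,50.0,239,4.8,L S1+2,Ade,cT2aN0M0,IB
4,60-69,46.3,162,3.5,L S8,SCC,pT2aN0M0,IB
5,80-89,52.6,283,5.4,R S7,Ade,pT2aN2M0,IB
6,60-69,63.0,164,2.6,R S6,SCC,pT1aN0M0,IA
7,70-79,48.6,146,3.0,R S3,Ade,pT1bN0M0,IA
8,70-79,46.5,144,3.1,R S2,Ade,pT2aN1M0,IIA
9,70-79,72.4,292,4.0,R S5,SCC,pT1aN0M0,IA
10,70-79,47.4,242,5.1,R S1,Ade,cT4N2M0,IIIB
11,30-39,40.7,147,3.6,R S8,MEDC,pT1bN0M0,IA
12,70-79,45.9,294,6.4,L S9,Ade,pT1bN0M0,IA
13,50-59,50.0,239,4.8,R S1,Ade,pT1aN0M0,IA
14,60-69,65.7,276,4.2,L S1+2,SCC,cT4N3M1b,IV
15,50-59,60.7,294,4.8,L S5,Ade,pT2aN1M1b,IV
16,60-69,52.1,243,4.7,R S2,SCC,cT4N3M0,IIIB
17,80-89,56.2,236,4.2,R S2,Ade,pT1aN0M0,IA
18,70-79,57.4,145,2.5,R S7,LCNEC,pT2aN2M0,IB
19,70-79,78.4,242,3.1,L S1+2,SCC,pT1bN0M0,IA
20,50-59,60.6,242,4.0,R S1,Ade,pT1bN2M0,IIIA
21,60-69,67.2,243,3.6,L S3,Ade,pT3N1M0,IIIA
22,80-89,48.5,240,5.0,R S10,Ade,pT2bN0M0,IIA
23,60-69,64.7,243,3.8,L S10,SCC,pT3N0M0,IIB
24,70-79,51.4,242,4.7,L S9,Ade,pT2bN0M0,IIA
25,60-69,54.8,292,5.3,R S3,Ade,pT2aN0M0,IIA
26,60-69,45.9,224,4.9,L S1+2,Ade,pT4N0M0,IIIA
27,80-89,62.7,242,3.9,L S1+2,SCC,cT3N0M0,IIB
28,70-79,55.4,146,2.6,R S4,Ade,cT2bN1M1b,IV
29,60-69,59.4,239,4.0,R S2,Ade,pT2bN0M0,IIA
30,70-79,53.0,145,2.7,L S10,PC,pT2aN1M0,IIB
31,70-79,55.3,237,4.3,R S1,PC,pT1aN0M0,IA
32,70-79,50.7,146,2.9,L S4,Ade,pT1aN3M0,IIIB
33,60-69,68.8,274,4.0,R S5,Ade,cT2aN2M1,IV
34,60-69,57.2,245,4.3,R S1,SCC,cT3N2M0,IIIA
35,70-79,45.6,242,5.3,R S1,Ade,pT1aN0M0,IA
36,80-89,54.6,274,5.0,L S1+2,Ade,pT3N1M0,IIIA
37,70-79,46.6,146,3.1,R S3,Ade,pT1aN2M0,IIIA
38,80-89,51.4,292,5.7,R S10,LCNEC,pT2aN0M0,IIA
39,80-89,74.8,273,3.6,R S4,Ade,pT2aN0M0,IIA
40,60-69,51.9,166,3.2,R S3,Ade,cT2aN0M1b,IV
41,70-79,40.8,164,4.0,R S3,Ade,pT2aN0M0,IB
42,50-59,45.2,166,3.7,L S3,SCC,cT4N2M0,IIIB
43,50-59,61.4,266,4.3,R S7,PC,pT2aN2M1,IV
44,50-59,72.2,290,4.0,L S10,SCC,cT2bN3M0,IIIB
45,60-69,62.4,166,2.7,R S1,LCNEC,pT2aN0M0,IIA
46,60-69,54.3,274,5.1,R S8,Ade,pT1aN0M0,IA
47,70-79,59.4,164,2.8,R S3,SCC,pT2aN0M0,IB
48,60-69,65.6,239,3.6,L S3,Ade,pT2aN1M0,IIA
49,70-79,61.9,292,4.7,R S3,SCC,pT1bN2M0,IIIA
50,60-69,60.9,290,4.8,R S6,ASCC,pT1aN1M0,IIA
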