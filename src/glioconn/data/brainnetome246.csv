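region_id,region_name,hemisphere,dmn_member
1,SFG_1_L,left,0
2,SFG_1_R,right,0
3,SFG_2_L,left,0
4,SFG_2_R,right,0
5,SFG_3_L,left,0
6,SFG_3_R,right,0
7,SFG_4_L,left,0
8,SFG_4_R,right,0
9,SFG_5_L,left,0
10,SFG_5_R,right,0
11,SFG_6_L,left,0
12,SFG_6_R,right,0
13,SFG_7_L,left,0
14,SFG_7_R,right,0
15,MFG_1_L,left,0
16,MFG_1_R,right,0
17,MFG_2_L,left,0
18,MFG_2_R,right,0
19,MFG_3_L,left,0
20,MFG_3_R,right,0
21,MFG_4_L,left,0
22,MFG_4_R,right,0
23,MFG_5_L,left,0
24,MFG_5_R,right,0
25,MFG_6_L,left,0
26,MFG_6_R,right,0
27,MFG_7_L,left,0
28,MFG_7_R,right,0
29,IFG_1_L,left,0
30,IFG_1_R,right,0
31,IFG_2_L,left,0
32,IFG_2_R,right,0
33,IFG_3_L,left,0
34,IFG_3_R,right,0
35,IFG_4_L,left,0
36,IFG_4_R,right,0
37,IFG_5_L,left,0
38,IFG_5_R,right,0
39,IFG_6_L,left,0
40,IFG_6_R,right,0
41,OrG_1_L,left,0
42,OrG_1_R,right,0
43,OrG_2_L,left,0
44,OrG_2_R,right,0
45,OrG_3_L,left,0
46,OrG_3_R,right,0
47,OrG_4_L,left,0
48,OrG_4_R,right,0
49,OrG_5_L,left,0
50,OrG_5_R,right,0
51,OrG_6_L,left,0
52,OrG_6_R,right,0
53,PrG_1_L,left,0
54,PrG_1_R,right,0
55,PrG_2_L,left,0
56,PrG_2_R,right,0
57,PrG_3_L,left,0
58,PrG_3_R,right,0
59,PrG_4_L,left,0
60,PrG_4_R,right,0
61,PrG_5_L,left,0
62,PrG_5_R,right,0
63,PrG_6_L,left,0
64,PrG_6_R,right,0
65,PCL_1_L,left,0
66,PCL_1_R,right,0
67,PCL_2_L,left,0
68,PCL_2_R,right,0
69,STG_1_L,left,0
70,STG_1_R,right,0
71,STG_2_L,left,0
72,STG_2_R,right,0
73,STG_3_L,left,0
74,STG_3_R,right,0
75,STG_4_L,left,0
76,STG_4_R,right,0
77,STG_5_L,left,0
78,STG_5_R,right,0
79,STG_6_L,left,0
80,STG_6_R,right,0
81,MTG_1_L,left,1
82,MTG_1_R,right,1
83,MTG_2_L,left,1
84,MTG_2_R,right,1
85,MTG_3_L,left,1
86,MTG_3_R,right,1
87,MTG_4_L,left,1
88,MTG_4_R,right,1
89,ITG_1_L,left,0
90,ITG_1_R,right,0
91,ITG_2_L,left,0
92,ITG_2_R,right,0
93,ITG_3_L,left,0
94,ITG_3_R,right,0
95,ITG_4_L,left,0
96,ITG_4_R,right,0
97,ITG_5_L,left,0
98,ITG_5_R,right,0
99,ITG_6_L,left,0
100,ITG_6_R,right,0
101,FuG_1_L,left,0
102,FuG_1_R,right,0
103,FuG_2_L,left,0
104,FuG_2_R,right,0
105,FuG_3_L,left,0
106,FuG_3_R,right,0
107,FuG_4_L,left,0
108,FuG_4_R,right,0
109,PhG_1_L,left,0
110,PhG_1_R,right,0
111,PhG_2_L,left,0
112,PhG_2_R,right,0
113,PhG_3_L,left,0
114,PhG_3_R,right,0
115,PhG_4_L,left,0
116,PhG_4_R,right,0
117,PhG_5_L,left,0
118,PhG_5_R,right,0
119,PhG_6_L,left,0
120,PhG_6_R,right,0
121,pSTS_1_L,left,0
122,pSTS_1_R,right,0
123,pSTS_2_L,left,0
124,pSTS_2_R,right,0
125,SPL_1_L,left,0
126,SPL_1_R,right,0
127,SPL_2_L,left,0
128,SPL_2_R,right,0
129,SPL_3_L,left,0
130,SPL_3_R,right,0
131,SPL_4_L,left,0
132,SPL_4_R,right,0
133,SPL_5_L,left,0
134,SPL_5_R,right,0
135,IPL_1_L,left,1
136,IPL_1_R,right,1
137,IPL_2_L,left,1
138,IPL_2_R,right,1
139,IPL_3_L,left,1
140,IPL_3_R,right,1
141,IPL_4_L,left,1
142,IPL_4_R,right,1
143,IPL_5_L,left,1
144,IPL_5_R,right,1
145,IPL_6_L,left,1
146,IPL_6_R,right,1
147,Pcun_1_L,left,0
148,Pcun_1_R,right,0
149,Pcun_2_L,left,0
150,Pcun_2_R,right,0
151,Pcun_3_L,left,0
152,Pcun_3_R,right,0
153,PoG_1_L,left,0
154,PoG_1_R,right,0
155,PoG_2_L,left,0
156,PoG_2_R,right,0
157,PoG_3_L,left,0
158,PoG_3_R,right,0
159,PoG_4_L,left,0
160,PoG_4_R,right,0
161,PoG_5_L,left,0
162,PoG_5_R,right,0
163,INS_1_L,left,0
164,INS_1_R,right,0
165,INS_2_L,left,0
166,INS_2_R,right,0
167,INS_3_L,left,0
168,INS_3_R,right,0
169,INS_4_L,left,0
170,INS_4_R,right,0
171,INS_5_L,left,0
172,INS_5_R,right,0
173,INS_6_L,left,0
174,INS_6_R,right,0
175,CG_1_L,left,1
176,CG_1_R,right,1
177,CG_2_L,left,1
178,CG_2_R,right,1
179,CG_3_L,left,1
180,CG_3_R,right,1
181,CG_4_L,left,1
182,CG_4_R,right,1
183,CG_5_L,left,1
184,CG_5_R,right,1
185,CG_6_L,left,1
186,CG_6_R,right,1
187,CG_7_L,left,1
188,CG_7_R,right,1
189,MVOcC_1_L,left,0
190,MVOcC_1_R,right,0
191,MVOcC_2_L,left,0
192,MVOcC_2_R,right,0
193,MVOcC_3_L,left,0
194,MVOcC_3_R,right,0
195,MVOcC_4_L,left,0
196,MVOcC_4_R,right,0
197,MVOcC_5_L,left,0
198,MVOcC_5_R,right,0
199,LOcC_1_L,left,0
200,LOcC_1_R,right,0
201,LOcC_2_L,left,0
202,LOcC_2_R,right,0
203,LOcC_3_L,left,0
204,LOcC_3_R,right,0
205,LOcC_4_L,left,0
206,LOcC_4_R,right,0
207,LOcC_5_L,left,0
208,LOcC_5_R,right,0
209,LOcC_6_L,left,0
210,LOcC_6_R,right,0
211,Amyg_1_L,left,0
212,Amyg_1_R,right,0
213,Amyg_2_L,left,0
214,Amyg_2_R,right,0
215,Hipp_1_L,left,0
216,Hipp_1_R,right,0
217,Hipp_2_L,left,0
218,Hipp_2_R,right,0
219,BG_1_L,left,0
220,BG_1_R,right,0
221,BG_2_L,left,0
222,BG_2_R,right,0
223,BG_3_L,left,0
224,BG_3_R,right,0
225,BG_4_L,left,0
226,BG_4_R,right,0
227,BG_5_L,left,0
228,BG_5_R,right,0
229,BG_6_L,left,0
230,BG_6_R,right,0
231,Tha_1_L,left,0
232,Tha_1_R,right,0
233,Tha_2_L,left,0
234,Tha_2_R,right,0
235,Tha_3_L,left,0
236,Tha_3_R,right,0
237,Tha_4_L,left,0
238,Tha_4_R,right,0
239,Tha_5_L,left,0
240,Tha_5_R,right,0
241,Tha_6_L,left,0
242,Tha_6_R,right,0
243,Tha_7_L,left,0
244,Tha_7_R,right,0
245,Tha_8_L,left,0
246,Tha_8_R,right,0
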