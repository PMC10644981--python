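index	name	hemisphere
0	L.Bankssts	L
1	L.CaudalAnteriorCingulate	L
2	L.CaudalMiddleFrontal	L
3	L.Cuneus	L
4	L.Entorhinal	L
5	L.Fusiform	L
6	L.InferiorParietal	L
7	L.InferiorTemporal	L
8	L.IsthmusCingulate	L
9	L.LateralOccipital	L
10	L.LateralOrbitoFrontal	L
11	L.Lingual	L
12	L.MedialOrbitoFrontal	L
13	L.MiddleTemporal	L
14	L.ParaHippocampal	L
15	L.ParaCentral	L
16	L.ParsOpercularis	L
17	L.ParsOrbitalis	L
18	L.ParsTriangularis	L
19	L.PeriCalcarine	L
20	L.PostCentral	L
21	L.PosteriorCingulate	L
22	L.PreCentral	L
23	L.PreCuneus	L
24	L.RostralAnteriorCingulate	L
25	L.RostralMiddleFrontal	L
26	L.SuperiorFrontal	L
27	L.SuperiorParietal	L
28	L.SuperiorTemporal	L
29	L.SupraMarginal	L
30	L.FrontalPole	L
31	L.TemporalPole	L
32	L.TransverseTemporal	L
33	L.Insula	L
34	L.Thalamus	L
35	L.Caudate	L
36	L.Putamen	L
37	L.Pallidum	L
38	L.Hippocampus	L
39	L.Amygdala	L
40	L.Accumbens	L
41	L.Cerebellum	L
42	R.Bankssts	R
43	R.CaudalAnteriorCingulate	R
44	R.CaudalMiddleFrontal	R
45	R.Cuneus	R
46	R.Entorhinal	R
47	R.Fusiform	R
48	R.InferiorParietal	R
49	R.InferiorTemporal	R
50	R.IsthmusCingulate	R
51	R.LateralOccipital	R
52	R.LateralOrbitoFrontal	R
53	R.Lingual	R
54	R.MedialOrbitoFrontal	R
55	R.MiddleTemporal	R
56	R.ParaHippocampal	R
57	R.ParaCentral	R
58	R.ParsOpercularis	R
59	R.ParsOrbitalis	R
60	R.ParsTriangularis	R
61	R.PeriCalcarine	R
62	R.PostCentral	R
63	R.PosteriorCingulate	R
64	R.PreCentral	R
65	R.PreCuneus	R
66	R.RostralAnteriorCingulate	R
67	R.RostralMiddleFrontal	R
68	R.SuperiorFrontal	R
69	R.SuperiorParietal	R
70	R.SuperiorTemporal	R
71	R.SupraMarginal	R
72	R.FrontalPole	R
73	R.TemporalPole	R
74	R.TransverseTemporal	R
75	R.Insula	R
76	R.Thalamus	R
77	R.Caudate	R
78	R.Putamen	R
79	R.Pallidum	R
80	R.Hippocampus	R
81	R.Amygdala	R
82	R.Accumbens	R
83	R.Cerebellum	R
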