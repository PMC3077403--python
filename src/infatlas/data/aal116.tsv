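id	name	hemisphere	lobe	division
1	Precentral_L	L	frontal	cerebrum
2	Precentral_R	R	frontal	cerebrum
3	Frontal_Sup_L	L	frontal	cerebrum
4	Frontal_Sup_R	R	frontal	cerebrum
5	Frontal_Sup_Orb_L	L	frontal	cerebrum
6	Frontal_Sup_Orb_R	R	frontal	cerebrum
7	Frontal_Mid_L	L	frontal	cerebrum
8	Frontal_Mid_R	R	frontal	cerebrum
9	Frontal_Mid_Orb_L	L	frontal	cerebrum
10	Frontal_Mid_Orb_R	R	frontal	cerebrum
11	Frontal_Inf_Oper_L	L	frontal	cerebrum
12	Frontal_Inf_Oper_R	R	frontal	cerebrum
13	Frontal_Inf_Tri_L	L	frontal	cerebrum
14	Frontal_Inf_Tri_R	R	frontal	cerebrum
15	Frontal_Inf_Orb_L	L	frontal	cerebrum
16	Frontal_Inf_Orb_R	R	frontal	cerebrum
17	Rolandic_Oper_L	L	frontal	cerebrum
18	Rolandic_Oper_R	R	frontal	cerebrum
19	Supp_Motor_Area_L	L	frontal	cerebrum
20	Supp_Motor_Area_R	R	frontal	cerebrum
21	Olfactory_L	L	frontal	cerebrum
22	Olfactory_R	R	frontal	cerebrum
23	Frontal_Sup_Medial_L	L	frontal	cerebrum
24	Frontal_Sup_Medial_R	R	frontal	cerebrum
25	Frontal_Med_Orb_L	L	frontal	cerebrum
26	Frontal_Med_Orb_R	R	frontal	cerebrum
27	Rectus_L	L	frontal	cerebrum
28	Rectus_R	R	frontal	cerebrum
29	Insula_L	L	insula	cerebrum
30	Insula_R	R	insula	cerebrum
31	Cingulum_Ant_L	L	limbic	cerebrum
32	Cingulum_Ant_R	R	limbic	cerebrum
33	Cingulum_Mid_L	L	limbic	cerebrum
34	Cingulum_Mid_R	R	limbic	cerebrum
35	Cingulum_Post_L	L	limbic	cerebrum
36	Cingulum_Post_R	R	limbic	cerebrum
37	Hippocampus_L	L	limbic	cerebrum
38	Hippocampus_R	R	limbic	cerebrum
39	ParaHippocampal_L	L	limbic	cerebrum
40	ParaHippocampal_R	R	limbic	cerebrum
41	Amygdala_L	L	subcortical	cerebrum
42	Amygdala_R	R	subcortical	cerebrum
43	Calcarine_L	L	occipital	cerebrum
44	Calcarine_R	R	occipital	cerebrum
45	Cuneus_L	L	occipital	cerebrum
46	Cuneus_R	R	occipital	cerebrum
47	Lingual_L	L	occipital	cerebrum
48	Lingual_R	R	occipital	cerebrum
49	Occipital_Sup_L	L	occipital	cerebrum
50	Occipital_Sup_R	R	occipital	cerebrum
51	Occipital_Mid_L	L	occipital	cerebrum
52	Occipital_Mid_R	R	occipital	cerebrum
53	Occipital_Inf_L	L	occipital	cerebrum
54	Occipital_Inf_R	R	occipital	cerebrum
55	Fusiform_L	L	temporal	cerebrum
56	Fusiform_R	R	temporal	cerebrum
57	Postcentral_L	L	parietal	cerebrum
58	Postcentral_R	R	parietal	cerebrum
59	Parietal_Sup_L	L	parietal	cerebrum
60	Parietal_Sup_R	R	parietal	cerebrum
61	Parietal_Inf_L	L	parietal	cerebrum
62	Parietal_Inf_R	R	parietal	cerebrum
63	SupraMarginal_L	L	parietal	cerebrum
64	SupraMarginal_R	R	parietal	cerebrum
65	Angular_L	L	parietal	cerebrum
66	Angular_R	R	parietal	cerebrum
67	Precuneus_L	L	parietal	cerebrum
68	Precuneus_R	R	parietal	cerebrum
69	Paracentral_Lobule_L	L	frontal	cerebrum
70	Paracentral_Lobule_R	R	frontal	cerebrum
71	Caudate_L	L	subcortical	cerebrum
72	Caudate_R	R	subcortical	cerebrum
73	Putamen_L	L	subcortical	cerebrum
74	Putamen_R	R	subcortical	cerebrum
75	Pallidum_L	L	subcortical	cerebrum
76	Pallidum_R	R	subcortical	cerebrum
77	Thalamus_L	L	subcortical	cerebrum
78	Thalamus_R	R	subcortical	cerebrum
79	Heschl_L	L	temporal	cerebrum
80	Heschl_R	R	temporal	cerebrum
81	Temporal_Sup_L	L	temporal	cerebrum
82	Temporal_Sup_R	R	temporal	cerebrum
83	Temporal_Pole_Sup_L	L	temporal	cerebrum
84	Temporal_Pole_Sup_R	R	temporal	cerebrum
85	Temporal_Mid_L	L	temporal	cerebrum
86	Temporal_Mid_R	R	temporal	cerebrum
87	Temporal_Pole_Mid_L	L	temporal	cerebrum
88	Temporal_Pole_Mid_R	R	temporal	cerebrum
89	Temporal_Inf_L	L	temporal	cerebrum
90	Temporal_Inf_R	R	temporal	cerebrum
91	Cerebelum_Crus1_L	L	cerebellum	cerebellum
92	Cerebelum_Crus1_R	R	cerebellum	cerebellum
93	Cerebelum_Crus2_L	L	cerebellum	cerebellum
94	Cerebelum_Crus2_R	R	cerebellum	cerebellum
95	Cerebelum_3_L	L	cerebellum	cerebellum
96	Cerebelum_3_R	R	cerebellum	cerebellum
97	Cerebelum_4_5_L	L	cerebellum	cerebellum
98	Cerebelum_4_5_R	R	cerebellum	cerebellum
99	Cerebelum_6_L	L	cerebellum	cerebellum
100	Cerebelum_6_R	R	cerebellum	cerebellum
101	Cerebelum_7b_L	L	cerebellum	cerebellum
102	Cerebelum_7b_R	R	cerebellum	cerebellum
103	Cerebelum_8_L	L	cerebellum	cerebellum
104	Cerebelum_8_R	R	cerebellum	cerebellum
105	Cerebelum_9_L	L	cerebellum	cerebellum
106	Cerebelum_9_R	R	cerebellum	cerebellum
107	Cerebelum_10_L	L	cerebellum	cerebellum
108	Cerebelum_10_R	R	cerebellum	cerebellum
109	Vermis_1_2	V	cerebellum	vermis
110	Vermis_3	V	cerebellum	vermis
111	Vermis_4_5	V	cerebellum	vermis
112	Vermis_6	V	cerebellum	vermis
113	Vermis_7	V	cerebellum	vermis
114	Vermis_8	V	cerebellum	vermis
115	Vermis_9	V	cerebellum	vermis
116	Vermis_10	V	cerebellum	vermis
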