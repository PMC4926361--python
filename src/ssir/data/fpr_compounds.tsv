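id	code	pKi1	fpr1_interest	pKi2	fpr2_interest
1	AAAA	4.000	0	4.000	0
2	AABB	4.000	0	4.000	0
3	AACA	3.610	0	4.000	0
4	ABAC	4.000	0	4.000	0
5	ABAA	4.000	0	4.000	0
6	ABBC	4.000	0	4.000	0
7	ABBB	4.000	0	4.000	0
8	ABCC	4.000	0	4.000	0
9	BBCA	4.000	0	2.130	1
10	CBDD	4.000	0	0.954	1
11	CBCE	3.426	0	1.079	1
12	CBCF	3.158	0	0.778	1
13	CCBG	4.000	0	2.703	0
14	CCBD	4.000	0	2.262	1
15	CCBC	4.000	0	1.839	1
16	CAAC	2.877	0	1.000	1
17	CAAH	2.550	1	1.322	1
18	CABC	3.527	0	0.778	1
19	CABH	4.000	0	1.176	1
20	CACC	2.978	0	0.699	1
21	CACH	4.000	0	1.491	1
22	CDAC	3.022	0	3.176	0
23	CDAH	2.519	1	2.360	1
24	CDBC	2.858	0	3.380	0
25	CDBH	1.663	1	1.845	1
26	CDCC	2.880	0	2.780	0
27	CDCH	2.446	1	1.763	1
28	CBAC	2.877	0	0.903	1
29	CBAH	4.000	0	1.708	1
30	CBBC	4.000	0	0.000	1
31	CBBH	4.000	0	1.322	1
32	CBCC	2.415	1	0.000	1
33	CBCH	2.822	0	1.041	1
34	BAAC	2.585	1	1.991	1
35	BAAH	3.050	0	2.243	1
36	BABC	2.639	0	2.021	1
37	BABH	3.253	0	1.991	1
38	BACC	3.126	0	2.212	1
39	BACH	2.943	0	2.423	1
40	BDAC	2.358	1	4.000	0
41	BDAH	1.799	1	2.772	0
42	BDBC	1.954	1	4.000	0
43	BDBH	0.301	1	2.210	1
44	BDCC	2.985	0	3.778	0
45	BDCH	2.675	0	2.613	1
46	BBAC	3.138	0	1.869	1
47	BBAH	4.000	0	2.709	0
48	BBBC	3.366	0	1.519	1
49	BBBH	4.000	0	2.648	0
50	BBCC	3.543	0	1.643	1
51	BBCH	4.000	0	2.657	0
52	DDBH	0.301	1	3.121	0
53	EEEA	3.472	0	4.000	0
54	DEFA	4.000	0	4.000	0
55	DEGA	4.000	0	4.000	0
56	DDGA	2.614	1	3.930	0
57	DEFC	4.000	0	4.000	0
58	DEFI	3.266	0	4.000	0
59	DDGF	2.888	0	4.000	0
60	DFGC	3.368	0	4.000	0
61	BEEC	3.291	0	4.000	0
62	BEEA	3.349	0	4.000	0
63	BEEH	3.102	0	3.580	0
64	DEEC	3.740	0	4.000	0
65	DEEA	3.504	0	4.000	0
66	DEEH	3.177	0	4.000	0
67	DEGH	2.901	0	4.000	0
68	BGEC	2.941	0	4.000	0
69	BGEA	2.766	0	4.000	0
70	BGEH	2.083	1	4.000	0
71	BGGC	2.748	0	4.000	0
72	BGGA	2.613	1	4.000	0
73	BGGH	3.305	0	4.000	0
74	BHEC	3.788	0	3.513	0
75	BHEA	3.561	0	3.768	0
76	BHEH	2.822	0	4.000	0
77	BHGC	2.161	1	4.000	0
78	BHGA	2.666	0	4.000	0
79	BHGH	3.054	0	4.000	0
80	DGEC	2.672	0	4.000	0
81	DGEH	1.716	1	4.000	0
82	DGGC	2.574	1	4.000	0
83	DGGA	2.336	1	4.000	0
84	DGGH	2.775	0	4.000	0
85	DHEC	4.000	0	3.410	0
86	DHEA	3.226	0	4.000	0
87	DHEH	2.772	0	4.000	0
88	DHGC	2.238	1	4.000	0
89	DHGA	2.708	0	4.000	0
90	DHGH	2.831	0	4.000	0
91	EGEJ	1.176	1	4.000	0
92	EGEK	0.845	1	4.000	0
93	EGEH	1.079	1	4.000	0
94	DGFJ	1.924	1	3.587	0
95	DGEL	1.301	1	4.000	0
96	DGEM	1.568	1	4.000	0
97	DGEJ	1.204	1	4.000	0
98	DGEN	1.146	1	4.000	0
99	DGEO	1.863	1	4.000	0
100	EGEP	0.477	1	4.000	0
101	EGHQ	2.691	0	4.000	0
102	EGIP	0.954	1	4.000	0
103	EGFP	1.886	1	4.000	0
104	DDBA	4.000	0	4.000	0
105	DDBC	1.447	1	4.000	0
106	BDBA	4.000	0	4.000	0
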