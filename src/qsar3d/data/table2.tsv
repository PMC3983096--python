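id	pic50_actual	pred_comfa	res_comfa	pred_comsia	res_comsia	role
1	6.027	5.905	-0.122	6.329	0.302	train
2	6.108	6.099	-0.009	6.005	-0.103	train
3	6.721	6.801	0.080	6.579	-0.142	train
4	6.770	6.568	-0.102	6.556	-0.114	test
5	6.638	6.715	0.077	6.734	0.096	train
6	5.921	5.893	-0.028	6.210	0.289	train
7	7.523	7.482	-0.041	7.601	0.078	train
8	8.000	7.907	-0.093	7.693	-0.307	train
9	7.509	7.605	0.096	7.309	-0.200	train
10	8.398	8.474	0.076	8.511	0.113	train
11	8.699	8.759	0.060	8.559	-0.140	train
12	8.699	8.736	0.037	8.368	-0.331	train
13	7.398	7.411	0.013	7.223	-0.175	train
14	6.456	6.806	0.350	6.931	0.475	train
15	7.398	7.189	-0.209	7.098	-0.300	test
16	7.523	7.205	-0.318	7.167	-0.356	train
17	7.097	7.089	-0.008	7.193	0.096	test
18	7.523	7.401	-0.122	7.347	-0.176	train
19	6.886	7.209	0.323	6.400	-0.486	train
20	7.000	6.890	-0.110	7.208	0.208	train
21	7.222	6.800	-0.422	7.377	0.155	test
22	8.000	7.823	-0.177	7.633	-0.367	test
23	8.097	7.907	-0.190	7.911	-0.186	train
24	7.699	7.409	-0.260	7.205	-0.494	test
25	5.397	5.517	0.120	5.591	0.194	train
26	5.000	5.299	0.299	5.394	0.394	test
27	5.482	5.478	-0.004	5.389	-0.093	train
28	5.854	5.726	-0.128	5.898	0.044	train
29	6.319	6.820	0.501	6.907	0.588	test
30	6.854	6.703	-0.151	7.017	0.163	train
31	4.959	5.028	0.069	4.784	-0.175	train
32	5.791	6.134	0.343	6.132	0.341	train
33	6.409	6.632	0.223	6.703	0.294	train
34	6.482	6.539	0.057	6.192	-0.290	train
35	6.658	6.605	-0.053	6.523	-0.135	test
36	7.000	6.898	-0.102	6.749	-0.251	train
37	6.886	6.769	-0.117	7.007	0.121	train
38	5.638	5.700	0.062	6.094	0.456	train
39	5.959	5.780	-0.179	6.043	0.084	train
40	5.602	5.460	-0.142	5.950	0.348	test
41	5.699	5.711	0.012	5.901	0.202	test
42	4.674	4.597	-0.077	4.406	-0.268	train
43	6.854	6.616	-0.238	7.010	0.156	train
44	5.456	5.502	0.046	5.512	0.056	train
45	6.000	6.003	0.003	6.237	0.237	train
46	6.036	6.104	0.068	5.989	-0.047	train
47	5.745	5.972	0.227	6.001	0.256	train
48	6.495	6.502	0.007	6.618	0.123	test
49	7.432	7.207	-0.225	7.629	0.197	train
50	7.301	7.405	0.104	7.198	-0.103	train
51	6.886	6.789	-0.097	7.099	0.213	train
52	7.569	7.500	-0.069	7.613	0.044	train
53	7.387	7.237	-0.150	7.403	0.016	train
54	6.886	7.066	0.180	7.100	0.214	test
55	4.801	4.834	0.033	4.748	-0.053	train
56	6.495	5.909	-0.586	6.001	-0.494	train
57	6.000	6.079	0.079	5.867	-0.133	train
58	5.553	5.604	0.051	5.713	0.160	train
59	5.569	5.803	0.234	5.737	0.168	test
60	5.523	5.543	0.020	5.624	0.101	train
61	4.790	4.643	-0.147	4.996	0.206	train
62	6.432	6.507	0.075	6.670	0.238	train
63	6.357	6.503	0.146	6.609	0.252	train
64	7.699	7.499	-0.200	7.803	0.104	train
65	8.000	7.865	-0.135	7.787	-0.213	train
66	7.523	7.570	0.047	7.632	0.109	train
67	7.699	7.398	-0.301	8.004	0.305	train
68	7.523	7.723	0.200	7.422	-0.101	train
69	7.699	7.609	-0.090	7.865	0.166	train
70	5.886	6.003	0.117	5.599	-0.287	train
71	6.252	6.331	0.079	6.271	0.019	train
72	6.569	6.796	0.227	6.358	-0.211	train
73	7.222	7.301	0.079	6.933	-0.289	train
74	4.917	5.230	0.313	5.274	0.357	train
75	6.886	6.558	-0.328	6.587	-0.299	test
76	6.959	6.960	0.001	6.789	-0.170	train
77	6.086	5.867	-0.219	6.372	0.286	train
78	7.097	7.109	0.012	6.903	-0.194	train
79	6.602	6.604	0.002	6.517	-0.085	train
80	5.903	5.913	0.010	6.043	0.140	train
81	5.108	5.140	0.032	5.006	-0.102	train
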