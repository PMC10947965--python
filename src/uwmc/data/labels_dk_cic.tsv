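id	name	lobe	hemisphere	in_abeta_set	in_tau_set
1	L superior frontal gyrus	frontal	L	1	0
2	L rostral middle frontal gyrus	frontal	L	1	0
3	L caudal middle frontal gyrus	frontal	L	1	0
4	L frontal pole	frontal	L	1	0
5	L lateral orbitofrontal gyrus	frontal	L	1	0
6	L medial orbitofrontal gyrus	frontal	L	1	0
7	L pars orbitalis	frontal	L	1	0
8	L pars triangularis	frontal	L	1	0
9	L rostral anterior cingulate cortex	frontal	L	1	0
10	L caudal anterior cingulate cortex	frontal	L	1	0
11	L inferior parietal gyrus	parietal	L	1	0
12	L supramarginal gyrus	parietal	L	1	0
13	L precuneus	parietal	L	1	0
14	L posterior cingulate cortex	parietal	L	1	0
15	L isthmus cingulate cortex	parietal	L	1	0
16	L superior temporal gyrus	temporal	L	1	0
17	L middle temporal gyrus	temporal	L	1	1
18	L inferior temporal gyrus	temporal	L	1	1
19	L banks of superior temporal sulcus	temporal	L	1	0
20	L insula	other	L	1	0
21	L anterior ventral striatum	other	L	1	0
22	L entorhinal cortex	temporal	L	0	1
23	L parahippocampal gyrus	temporal	L	0	1
24	L amygdala	temporal	L	0	1
25	L fusiform gyrus	temporal	L	0	1
26	L lateral occipital gyrus	occipital	L	0	0
27	L lingual gyrus	occipital	L	0	0
28	L cuneus	occipital	L	0	0
29	L pericalcarine cortex	occipital	L	0	0
30	R superior frontal gyrus	frontal	R	1	0
31	R rostral middle frontal gyrus	frontal	R	1	0
32	R caudal middle frontal gyrus	frontal	R	1	0
33	R frontal pole	frontal	R	1	0
34	R lateral orbitofrontal gyrus	frontal	R	1	0
35	R medial orbitofrontal gyrus	frontal	R	1	0
36	R pars orbitalis	frontal	R	1	0
37	R pars triangularis	frontal	R	1	0
38	R rostral anterior cingulate cortex	frontal	R	1	0
39	R caudal anterior cingulate cortex	frontal	R	1	0
40	R inferior parietal gyrus	parietal	R	1	0
41	R supramarginal gyrus	parietal	R	1	0
42	R precuneus	parietal	R	1	0
43	R posterior cingulate cortex	parietal	R	1	0
44	R isthmus cingulate cortex	parietal	R	1	0
45	R superior temporal gyrus	temporal	R	1	0
46	R middle temporal gyrus	temporal	R	1	1
47	R inferior temporal gyrus	temporal	R	1	1
48	R banks of superior temporal sulcus	temporal	R	1	0
49	R insula	other	R	1	0
50	R anterior ventral striatum	other	R	1	0
51	R entorhinal cortex	temporal	R	0	1
52	R parahippocampal gyrus	temporal	R	0	1
53	R amygdala	temporal	R	0	1
54	R fusiform gyrus	temporal	R	0	1
55	R lateral occipital gyrus	occipital	R	0	0
56	R lingual gyrus	occipital	R	0	0
57	R cuneus	occipital	R	0	0
58	R pericalcarine cortex	occipital	R	0	0
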