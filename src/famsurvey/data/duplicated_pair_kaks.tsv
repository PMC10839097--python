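gene1	gene2	ka	ks	ka_ks	mode	negative_selection
CteZFP20	CteZFP53	0.2930	0.4003	0.7320	tandem	yes
CteZFP63	CteZFP84	0.2509	0.3684	0.6811	tandem	yes
CteZFP91	CteZFP99	0.0026	0.0000	0.0000	segment	yes
CteZFP31	CteZFP28	0.0382	0.0568	0.6724	segment	yes
CteZFP96	CteZFP5	0.0000	0.0000	0.0000	segment	yes
CteZFP12	CteZFP87	0.5528	1.6257	0.3400	segment	yes
CteZFP80	CteZFP88	0.3036	1.0920	0.2780	segment	yes
CteZFP16	CteZFP37	0.2688	2.0345	0.1321	segment	yes
CteZFP97	CteZFP43	0.3220	1.2636	0.2548	segment	yes
CteZFP10	CteZFP14	0.5717	2.3418	0.2441	segment	yes
CteZFP77	CteZFP69	0.2514	1.1514	0.2184	segment	yes
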