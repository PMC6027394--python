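regulon_id	n_operons	deg	tf_template	mapped_tf	mapped_locus
2	82	Y	spo0A	llrC	llmg_0414
3	32	Y	FoxQ1	N/A	N/A
4	20	Y	SPT2	N/A	N/A
7	49	Y	lhfB	hllA	llmg_0496
10	5	N	GAL80	llmg_0271	llmg_0271
12	259	Y	CovR	llrA	llmg_0908
15	19	Y	c4494	ccpA	llmg_0775
20	79	Y	NHP6A	N/A	N/A
28	5	Y	1Z916	N/A	N/A
31	65	Y	ihfA	hllA	llmg_0496
37	10	N	CovR	llrA	llmg_0908
40	7	Y	Awh	N/A	N/A
44	12	N	YBR182C	N/A	N/A
47	5	N	RHE_PF00288	ccpA	llmg_0775
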