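template_gene	template_organism	functional_module	mapped_locus	regulons
ldh	Lactococcus lactis	LDH	llmg_1120	NHP6A;llrA
ldhB	Lactococcus lactis	LDH	llmg_0392	NHP6A;llrA
ldhB	Lactococcus lactis	LDH	llmg_0475	NHP6A;llrA
ldhX	Lactococcus lactis	LDH	llmg_1429	NHP6A;llrA
gadB	Lactococcus lactis	GAD	llmg_1179
gadC	Lactococcus lactis	GAD	llmg_1178
arcA	Lactococcus lactis	ADI pathway	llmg_2313	NHP6A;llrA;llrC;hllA
arcB	Lactococcus lactis	ADI pathway	llmg_2312	NHP6A;llrA;llrC;hllA
arcC1	Lactococcus lactis	ADI pathway	llmg_2310	NHP6A;llrA;llrC;hllA
arcC2	Lactococcus lactis	ADI pathway	llmg_2309	NHP6A;llrA;llrC;hllA
argF	Lactococcus lactis	ADI pathway	llmg_1754	NHP6A;llrA;llrC;hllA
ureA/B/C	Bacteria	Urea degradation	llmg_1508
atpE	Lactococcus lactis	F0/F1ATPase	llmg_1952	llrA;Regulon8
atpB	Lactococcus lactis	F0/F1ATPase	llmg_1951	llrA;Regulon8
atpF	Lactococcus lactis	F0/F1ATPase	llmg_1950	llrA;Regulon8
atpH	Lactococcus lactis	F0/F1ATPase	llmg_1949	llrA;Regulon8
atpA	Lactococcus lactis	F0/F1ATPase	llmg_1948	llrA;Regulon8
atpG	Lactococcus lactis	F0/F1ATPase	llmg_1947	llrA;Regulon8
atpD	Lactococcus lactis	F0/F1ATPase	llmg_1946	llrA;Regulon8
atpC	Lactococcus lactis	F0/F1ATPase	llmg_1945	llrA;Regulon8
rcfB	Lactococcus lactis	Acid response	llmg_2512	Regulon39
dnaK	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_1574	llrA
groEL	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_0411	llrA
groES	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_0410	llrA
grpE	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_1575	llrA
clpE	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_0528	llrA
clpC	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_0615	llrA
clpP	Lactococcus lactis/Escherichia coli K12	Protein repair and protease	llmg_0638	llrA
dltC/agK/SGP/ffh	Lactococcus lactis/Bacillus subtilis	Envelope alterations	llmg_0878	NHP6A;llrA
recA	Lactococcus lactis	DNA repair	llmg_0374	Regulon39
uvr	Lactococcus lactis	DNA repair	llmg_0534	Regulon39
smn	Lactococcus lactis	DNA repair	llmg_1718	Regulon39
recA/uvr/smn	Lactococcus lactis	DNA repair	llmg_1221	Regulon39
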