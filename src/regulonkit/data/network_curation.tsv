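source_type	source_id	edge_type	target_type	target_id	provenance
sensor	H+_sensor	node			literature
transmembrane_protein	F0F1_ATPase	node			literature
transmembrane_protein	unnamed_transmembrane	node			literature
tf_gene	rcfB	node			literature
sensor	H+_sensor	uncertain	tf_gene	rcfB	literature
tf_gene	rcfB	uncertain	regulon	2	literature
tf_gene	rcfB	uncertain	regulon	7	literature
tf_gene	rcfB	uncertain	regulon	8	literature
tf_gene	rcfB	uncertain	regulon	12	literature
tf_gene	rcfB	uncertain	regulon	15	literature
tf_gene	rcfB	uncertain	regulon	20	literature
tf_gene	rcfB	uncertain	regulon	31	literature
tf_gene	rcfB	uncertain	regulon	39	literature
tf_gene	rcfB	uncertain	functional_module	Acid response	literature
transmembrane_protein	F0F1_ATPase	uncertain	functional_module	F0/F1ATPase	literature
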