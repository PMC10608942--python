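gene_id	contig_id	mag_id	length_bp	ko_id	ec_ids	annot_identity_pct	annot_evalue
g1	c1	M1	900	K1	NA	95	1e-30
g2	c1	M1	600	K2	NA	50	1e-20
g3	c2	M1	300	K1	NA	25	1e-30
g4	c3	M2	900	K1	NA	80	1e-15
g5	c3	M2	450	K3	NA	99	1e-5
g6	c4	M2	600	NA	NA	NA	NA
g7	c5	UNBINNED	300	K2	NA	70	1e-12
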