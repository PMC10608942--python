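metaprotein_id	peptide_set_id	gene_ids	D1_r1	D1_r2	D2_r1
mp1	pepA	g1	10	8	1
mp2	pepB	g2	4	6	1
mp3	pepC	g4	6	4	17
mp4	pepD	g6	2	2	1
mp5	pepE	g7	3	1	0
mp6	pepF	g2,g4	5	5	5
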