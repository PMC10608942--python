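gene_id	D1_r1	D1_r2	D2_r1
g1	30	28	5
g2	20	22	5
g3	10	12	0
g4	40	38	80
g5	6	4	3
g6	14	10	5
g7	10	12	2
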