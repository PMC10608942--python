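sample_id	condition_id	replicate	unmapped_reads
D1_r1	D1	1	25
D1_r2	D1	2	10
D2_r1	D2	1	50
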