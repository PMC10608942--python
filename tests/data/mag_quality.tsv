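mag_id	completeness_pct	contamination_pct	taxonomy
M1	80	2	d__Bacteria;p__Bacillota
M2	100	5	d__Archaea;p__Halobacteriota
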