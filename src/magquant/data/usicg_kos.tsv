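ko_id	description
K02863	large subunit ribosomal protein L1
K02886	large subunit ribosomal protein L2
K02906	large subunit ribosomal protein L3
K02926	large subunit ribosomal protein L4
K02931	large subunit ribosomal protein L5
K02933	large subunit ribosomal protein L6
K02967	small subunit ribosomal protein S2
K02982	small subunit ribosomal protein S3
K02986	small subunit ribosomal protein S4
K02992	small subunit ribosomal protein S7
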