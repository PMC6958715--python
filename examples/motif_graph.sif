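PMAIP1_gen	1	PMAIP1_prot
TP53_prot	1	CCNG1_gen
TP53_prot	1	PMAIP1_gen
TP53_prot	1	SHISA5_gen
TP53_prot	1	TP73_gen
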