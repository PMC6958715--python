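gene,log2fc,padj
PMAIP1,2.8,3e-09
CCNG1,-1.9,1e-08
SHISA5,-2.4,5e-10
TP73,-1.2,2e-07
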