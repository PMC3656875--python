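name	recognition	cut_offset	remnant	methylation_sensitive
PstI	CTGCAG	1	TGCAG	1
EcoT22I	ATGCAT	1	TGCAT	0
ApeKI	GCWGC	1	CWGC	1
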