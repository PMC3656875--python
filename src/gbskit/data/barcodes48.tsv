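sample	barcode	breed	blank
Holstein01	TGACGCCA	Holstein	0
Holstein02	CAGATA	Holstein	0
Holstein03	GAAGTG	Holstein	0
Holstein04	TAGCGGAT	Holstein	0
Holstein05	TATTCGCAT	Holstein	0
Holstein06	ATAGAT	Holstein	0
Angus01	CCGAACA	Angus	0
Angus02	GGAAGACAT	Angus	0
Angus03	GGCTTA	Angus	0
Angus04	AACGCACATT	Angus	0
Angus05	GAGCGACAT	Angus	0
Angus06	CCTTGCCATT	Angus	0
Hereford01	GGTATA	Hereford	0
Hereford02	TCTTGG	Hereford	0
Hereford03	GGTGT	Hereford	0
Brangus01	GGATA	Brangus	0
Brangus02	CTAAGCA	Brangus	0
Brangus03	ATTAT	Brangus	0
Brangus04	GCGCTCA	Brangus	0
Brangus05	ACTGCGAT	Brangus	0
Brangus06	TTCGTT	Brangus	0
Brangus07	ATATAA	Brangus	0
Brangus08	TGGCAACAGA	Brangus	0
Brangus09	CTCGTCG	Brangus	0
Brangus10	GCCTACCT	Brangus	0
Brangus11	CACCA	Brangus	0
Brangus12	AATTAG	Brangus	0
Brangus13	GGAACGA	Brangus	0
Brangus14	ACAACT	Brangus	0
Brangus15	ACTGCT	Brangus	0
Brangus16	CGTGGACAGT	Brangus	0
Brangus17	TGGCACAGA	Brangus	0
Brangus18	TGCTT	Brangus	0
Brangus19	GCAAGCCAT	Brangus	0
Brangus20	CGCACCAATT	Brangus	0
Brangus21	CTCGCGG	Brangus	0
Brangus22	AACTGG	Brangus	0
Brangus23	ATGAGCAA	Brangus	0
Brangus24	CTTGA	Brangus	0
Brangus25	GCGTCCT	Brangus	0
Brangus26	ACCAGGA	Brangus	0
Brangus27	CCACTCA	Brangus	0
WhiteFulani01	TCACGGAAG	WhiteFulani	0
WhiteFulani02	TATCA	WhiteFulani	0
Muturu01	TAGCCAA	Muturu	0
Muturu02	ATATCGCCA	Muturu	0
Muturu03	CTCTA	Muturu	0
Blank	GGTGCACATT	none	1
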