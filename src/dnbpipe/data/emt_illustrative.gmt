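epithelial	illustrative non-canonical epithelial marker set (not a curated signature)	CDH1	EPCAM	KRT5	KRT14	KRT18	CLDN4	DSP	OCLN
mesenchymal	illustrative non-canonical mesenchymal marker set (not a curated signature)	VIM	FN1	CDH2	SNAI1	SNAI2	ZEB1	TWIST1	FBN1
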