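NOTCH20	20-gene Notch transcriptomic signature for breast cancer, genes in rank order	SEMA5B	NRARP	PLAT	PRELP	HEYL	FAT2	HEY1	KRT5	NPR3	KRT14	FLT1	RHOV	TNFRSF19	JAG1	MT1X	HEY2	PDGFRB	ZNF469	VSNL1	KIT
NOTCH_CORE	Notch core signature: the four receptors and five canonical ligands	NOTCH1	NOTCH2	NOTCH3	NOTCH4	JAG1	JAG2	DLL1	DLL3	DLL4
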