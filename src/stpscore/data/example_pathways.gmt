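AR	illustrative androgen receptor target genes (synthetic demo set, non-authoritative)	KLK2	KLK3	TMPRSS2	FKBP5	NKX3-1	NDRG1
MAPK	illustrative MAPK/AP-1 target genes (synthetic demo set, non-authoritative)	FOS	EGR1	DUSP1	SPRY2	ETV4	PHLDA1
NFKB	illustrative NFkB target genes (synthetic demo set, non-authoritative)	NFKBIA	TNFAIP3	CXCL8	ICAM1	BIRC3	TRAF1
TGFB	illustrative TGF-beta/SMAD target genes (synthetic demo set, non-authoritative)	SERPINE1	SMAD7	SKIL	PMEPA1	ANGPTL4	CDKN2B
JAK-STAT1/2	illustrative STAT1/2 interferon target genes (synthetic demo set, non-authoritative)	IRF1	GBP1	ISG15	MX1	OAS1	IFIT1
JAK-STAT3	illustrative STAT3 target genes (synthetic demo set, non-authoritative)	SOCS3	BCL3	OSMR	PIM1	MCL1	VEGFA
WNT	illustrative Wnt/TCF target genes (synthetic demo set, non-authoritative)	AXIN2	LGR5	ASCL2	RNF43	ZNRF3	SP5
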