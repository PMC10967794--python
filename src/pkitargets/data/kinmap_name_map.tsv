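uniprot	kinase_name
P00533	EGFR
P35968	KDR
P09619	PDGFRb
P00519	ABL1
O43353	RIPK2
O14757	CHK1
O75116	ROCK2
Q96GD4	AurB
P07949	RET
P36897	TGFbR1
P06239	LCK
P04626	HER2
Q02750	MAP2K1
P28482	ERK2
P68400	CK2a1
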