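Wnt	synthetic stand-in gene set (Wnt signalling membership of the 20 reported genes)	AXIN2	CTNNB1	CTBP1	WNT5A	PRKCA	PPP3CA	RAC2	PPP3R1	JUN
MAPK	synthetic stand-in gene set (MAPK signalling membership of the 20 reported genes)	DDIT3	PDGFRA	KITLG	FOS	DUSP5	MAP3K6	PRKCA	PPP3CA	RAC2	PPP3R1	JUN	KRAS
Ras	synthetic stand-in gene set (Ras signalling membership of the 20 reported genes)	RAP1B	PLD1	KRAS	LAT	RGL1	KITLG	PDGFRA	PRKCA	RAC2	JUN
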