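gene	cohort	mei_class	tools
APC	Radboudumc	L1	SCRAMble,MELT
AVPR2	Radboudumc	L1	SCRAMble,MELT
BRCA2	Radboudumc	Alu	MELT
CC2D2A	Radboudumc	Alu	MELT
COL11A1	Radboudumc	na	SCRAMble
COL6A2	Solve-RD	Alu	SCRAMble,MELT
NIPBL	Solve-RD	Alu	SCRAMble,MELT
NKX2-1	Solve-RD	Alu	SCRAMble
TTN	Radboudumc	Alu	SCRAMble,MELT
USH2A	Radboudumc	Alu	SCRAMble
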