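# Synthetic coiled-coil pair library (fixture; sequences are NOT the
# published toolkit peptides, only idealized heptad stand-ins).
name	seq_a	seq_b	orientation	group	variant
P1SN:P2SN	ASEIAQLESEIQSLEAEISALEQEIAQLESGS	ASKIAQLKSKIQSLKAKISALKQKIAQLKSGS	parallel	P12	SN
P3SN:P4SN	ASEIASLEQEISQLEAEIQALESEIASLEQGS	ASKIASLKQKISQLKAKIQALKSKIASLKQGS	parallel	P34	SN
P5SN:P6SN	ASEIQALESEIASLEQEISQLEAEIQALESGS	ASKIQALKSKIASLKQKISQLKAKIQALKSGS	parallel	P56	SN
P7SN:P8SN	ASEIQSLEAEISALEQEIAQLESEIQSLEAGS	ASKIQSLKAKISALKQKIAQLKSKIQSLKAGS	parallel	P78	SN
P9SN:P10SN	ASEISALEQEIAQLESEIQSLEAEISALEQGS	ASKISALKQKIAQLKSKIQSLKAKISALKQGS	parallel	P910	SN
P11SN:P12SN	ASEISQLEAEIQALESEIASLEQEISQLEAGS	ASKISQLKAKIQALKSKIASLKQKISQLKAGS	parallel	P1112	SN
P5SH:P6SH	ASEIRELEKEIEKLEREIKRLEEEIRELEKGS	ASKIRELKKKIEKLKRKIKRLKEKIRELKKGS	parallel	P56	SH
P7SH:P8SH	ASEIRKLEEEIKELEREIERLEKEIRKLEEGS	ASKIRKLKEKIKELKRKIERLKKKIRKLKEGS	parallel	P78	SH
P9SH:P10SH	ASEIKELEREIERLEKEIRKLEEEIKELERGS	ASKIKELKRKIERLKKKIRKLKEKIKELKRGS	parallel	P910	SH
GCNSN	ASEINALKQEIAQLKNEIQNLKAEINALKQGS	ASEINALKQEIAQLKNEIQNLKAEINALKQGS	parallel	GCN	SN
APHSN	ASEIANLKQEINQLKAEIQALKNEIANLKQGS	ASEIANLKQEINQLKAEIQALKNEIANLKQGS	antiparallel	APH	SN
BCR	ASEIQNLKAEINALKQEIAQLKNEIQNLKAGS	ASEIQNLKAEINALKQEIAQLKNEIQNLKAGS	antiparallel	BCR	SN
BCRSH	ASEIRRLKEEIRELKREIERLKREIRRLKEGS	ASEIRRLKEEIRELKREIERLKREIRRLKEGS	antiparallel	BCR	SH
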