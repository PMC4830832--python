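# Prior-knowledge network for NGF-driven PC12 differentiation
# (synthetic reconstruction): 63 nodes, 109 signed interactions.
# Columns: source <TAB> sign(+1/-1) <TAB> target <TAB> fixed(0/1).
# Transcription choices:
# - Fixed interactions (column 4 = 1): NGF->PI3K, NGF->RAS, NGF->PLC,
#   AP1->Npy, MEK/ERK & JNK -> Jund, MEK/ERK & JNK -> Junb,
#   Fosl1 & Jund -> AP1, Mmp10->RAS, RAS->MEK, PLC->MEK (the '&' gates are
#   realized as paired edges; logic synthesis is OR over activators).
# - Pathways: TrkA/SHC/GRB2/SOS adapters, RAF/MEK/ERK, PI3K/PDK1/AKT,
#   MEKK1/MKK4/MKK7 -> JNK and P38/MK2, PLC/PKC, uPA-plasmin-MMP-integrin-FAK
#   autocrine loop, IL6/STAT3, NPY/NPY1R, TNFRSF12A.
# - Roles are in the sidecar annotation table (stimulus NGF; inhibited MEK,
#   JNK, PI3K; 27 measured transcripts; linker nodes hidden).
NGF	1	TrkA	0
TrkA	1	SHC	0
TrkA	1	SRC	0
SHC	1	GRB2	0
GRB2	1	SOS	0
SOS	1	RAS	0
NGF	1	RAS	1
NGF	1	PI3K	1
NGF	1	PLC	1
RAS	1	RAF	0
RAF	1	MEK	0
RAS	1	MEK	1
PLC	1	MEK	1
MEK	1	ERK	0
ERK	1	RSK	0
RSK	1	CREB	0
ERK	1	ELK1	0
ERK	1	SRF	0
ELK1	1	Fos	0
SRF	1	Fos	0
CREB	1	Fos	0
Dusp6	-1	ERK	0
PI3K	1	PDK1	0
PDK1	1	AKT	0
PI3K	1	AKT	0
PTEN	-1	PI3K	0
AKT	1	CREB	0
AKT	1	Maff	0
AKT	1	Klf10	0
RAS	1	MEKK1	0
MEKK1	1	MKK4	0
MEKK1	1	MKK7	0
MKK4	1	JNK	0
MKK7	1	JNK	0
MKK4	1	P38	0
P38	1	MK2	0
MK2	1	Zfp36	0
ERK	1	Junb	1
JNK	1	Junb	1
ERK	1	Jund	1
JNK	1	Jund	1
P38	1	Atf3	0
JNK	1	Atf3	0
PLC	1	PKC	0
PKC	1	RAF	0
NPY1R	1	PLC	0
Npy	1	NPY1R	0
Fosl1	1	AP1	1
Jund	1	AP1	1
Fos	1	AP1	0
Junb	1	AP1	0
Zfp36	-1	AP1	0
Atf3	-1	AP1	0
ERK	1	Fosl1	0
ERK	1	Egr1	0
JNK	1	Egr1	0
ERK	1	Klf4	0
ERK	1	Btg2	0
JNK	1	Btg2	0
ERK	1	Zfp36	0
JNK	1	Klf2	0
JNK	1	Klf6	0
ERK	1	Cited2	0
ERK	1	Dusp6	0
JNK	1	Fosl1	0
AP1	1	Npy	1
AP1	1	Plau	0
AP1	1	Plaur	0
AP1	1	Serpine1	0
AP1	1	Plat	0
AP1	1	Vgf	0
AP1	1	Gadd45a	0
AP1	1	Dclk1	0
AP1	1	Klf5	0
AP1	1	Mmp3	0
Plau	1	Plasmin	0
Plat	1	Plasmin	0
Plasminogen	1	Plasmin	0
Serpine1	-1	Plasmin	0
Plasmin	1	Mmp3	0
Plasmin	1	Mmp10	0
Mmp3	1	Itga1	0
Mmp10	1	Itga1	0
Mmp10	1	RAS	1
Plaur	1	Itga1	0
Itga1	1	ITGB1	0
ITGB1	1	FAK	0
Plaur	1	FAK	0
FAK	1	SRC	0
SRC	1	SHC	0
FAK	1	SHC	0
FAK	1	MEKK1	0
AP1	1	IL6	0
IL6	1	IL6R	0
IL6R	1	STAT3	0
STAT3	1	Klf5	0
STAT3	1	Vgf	0
AP1	1	TNFRSF12A	0
TNFRSF12A	1	MEKK1	0
CREB	1	Npy	0
CREB	1	Vgf	0
JNK	1	Cited2	0
ERK	1	Klf2	0
P38	1	Gadd45a	0
AP1	1	Mmp10	0
JNK	1	Klf4	0
STAT3	1	Dclk1	0
AP1	1	Itga1	0
AP1	1	Fosl1	0
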