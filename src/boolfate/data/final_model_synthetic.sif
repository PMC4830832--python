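# Final Boolean model of NGF-driven PC12 differentiation (synthetic reconstruction).
# 32 nodes, 52 interactions. Transcription choices:
# - MEK and ERK are lumped as MEK_ERK (compressed linear transition).
# - Transient genes Klf4/Btg2/Zfp36 are shut off by a latching GrowthArrest
#   effect node (auto-inhibition once their growth-arrest effect is mediated);
#   Zfp36 additionally delays AP1 assembly (AP1 = Fosl1 & Jund & !Zfp36).
# - Autocrine positive feedback: AP1 -> uPA -> plasmin -> Mmp10 -> Itga1 ->
#   FAK -> RAS/JNK, plus AP1 -> Npy -> Npy1r -> PLC -> MEK_ERK.
# - CellDifferentiation requires uPAR signaling together with late genes.
FAK	1	RAS
Mmp10	1	RAS
NGF	1	RAS
PLC	1	MEK_ERK
RAS	1	MEK_ERK
NGF	1	PI3K
PI3K	1	AKT
FAK	1	JNK
NGF	1	JNK
NGF	1	PLC
Npy1r	1	PLC
Itga1	1	FAK
AP1	1	uPA
uPA	1	Plasmin
Plasmin	1	Mmp10
Mmp10	1	Itga1
uPA	1	uPAR
MEK_ERK	1	Fosl1
MEK_ERK	1	Fos
JNK	1	Junb
MEK_ERK	1	Junb
JNK	1	Jund
MEK_ERK	1	Jund
Fosl1	1	AP1
Jund	1	AP1
Zfp36	-1	AP1
MEK_ERK	1	Egr1
JNK	1	Klf2
uPAR	1	Klf2
GrowthArrest	-1	Klf4
MEK_ERK	1	Klf4
GrowthArrest	-1	Btg2
MEK_ERK	1	Btg2
GrowthArrest	-1	Zfp36
MEK_ERK	1	Zfp36
Btg2	1	GrowthArrest
GrowthArrest	1	GrowthArrest
Klf4	1	GrowthArrest
AP1	1	Klf5
uPAR	1	Klf5
AP1	1	Klf6
JNK	1	Klf6
AKT	1	Klf10
JNK	1	Klf10
AKT	1	Maff
JNK	1	Maff
MEK_ERK	1	Cited2
AP1	1	Npy
Npy	1	Npy1r
Klf5	1	CellDifferentiation
Npy	1	CellDifferentiation
uPAR	1	CellDifferentiation
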