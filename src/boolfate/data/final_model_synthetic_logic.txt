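# Final Boolean model of NGF-driven PC12 differentiation (synthetic reconstruction).
# 32 nodes, 52 interactions. Transcription choices:
# - MEK and ERK are lumped as MEK_ERK (compressed linear transition).
# - Transient genes Klf4/Btg2/Zfp36 are shut off by a latching GrowthArrest
#   effect node (auto-inhibition once their growth-arrest effect is mediated);
#   Zfp36 additionally delays AP1 assembly (AP1 = Fosl1 & Jund & !Zfp36).
# - Autocrine positive feedback: AP1 -> uPA -> plasmin -> Mmp10 -> Itga1 ->
#   FAK -> RAS/JNK, plus AP1 -> Npy -> Npy1r -> PLC -> MEK_ERK.
# - CellDifferentiation requires uPAR signaling together with late genes.
NGF = NGF
RAS = NGF | Mmp10 | FAK
MEK_ERK = RAS | PLC
PI3K = NGF
AKT = PI3K
JNK = NGF | FAK
PLC = NGF | Npy1r
FAK = Itga1
uPA = AP1
Plasmin = uPA
Mmp10 = Plasmin
Itga1 = Mmp10
uPAR = uPA
Fosl1 = MEK_ERK
Fos = MEK_ERK
Junb = MEK_ERK & JNK
Jund = MEK_ERK & JNK
AP1 = Fosl1 & Jund & !Zfp36
Egr1 = MEK_ERK
Klf2 = JNK | uPAR
Klf4 = MEK_ERK & !GrowthArrest
Btg2 = MEK_ERK & !GrowthArrest
Zfp36 = MEK_ERK & !GrowthArrest
GrowthArrest = GrowthArrest | Klf4 | Btg2
Klf5 = uPAR & AP1
Klf6 = JNK | AP1
Klf10 = AKT & JNK
Maff = AKT & JNK
Cited2 = MEK_ERK
Npy = AP1
Npy1r = Npy
CellDifferentiation = uPAR & Klf5 & Npy
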