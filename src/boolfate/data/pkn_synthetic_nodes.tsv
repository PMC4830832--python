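# Node roles for pkn_synthetic.sif (synthetic reconstruction).
node	role
NGF	stimulus
TrkA	hidden
SHC	hidden
SRC	hidden
GRB2	hidden
SOS	hidden
RAS	hidden
PI3K	inhibited
PLC	hidden
RAF	hidden
MEK	inhibited
ERK	hidden
RSK	hidden
CREB	hidden
ELK1	hidden
SRF	hidden
Fos	measured
Dusp6	measured
PDK1	hidden
AKT	hidden
PTEN	hidden
Maff	measured
Klf10	measured
MEKK1	hidden
MKK4	hidden
MKK7	hidden
JNK	inhibited
P38	hidden
MK2	hidden
Zfp36	measured
Junb	measured
Jund	measured
Atf3	measured
PKC	hidden
NPY1R	hidden
Npy	measured
Fosl1	measured
AP1	hidden
Egr1	measured
Klf4	measured
Btg2	measured
Klf2	measured
Klf6	measured
Cited2	measured
Plau	measured
Plaur	measured
Serpine1	measured
Plat	measured
Vgf	measured
Gadd45a	measured
Dclk1	measured
Klf5	measured
Mmp3	measured
Plasmin	hidden
Plasminogen	hidden
Mmp10	measured
Itga1	measured
ITGB1	hidden
FAK	hidden
IL6	hidden
IL6R	hidden
STAT3	hidden
TNFRSF12A	hidden
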