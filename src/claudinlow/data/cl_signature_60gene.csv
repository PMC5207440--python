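symbol,direction
ADAMDEC1,up
ANXA1,up
BTN3A3,up
CASP1,up
CD36,up
CD3D,up
CFLAR,up
COLEC12,up
CTSK,up
CTSS,up
CXCL9,up
DPT,up
EPAS1,up
FHL1,up
FUCA1,up
GPX3,up
LAPTM5,up
LGALS2,up
LTB,up
LXN,up
MAF,up
PLAC8,up
PSMB10,up
AKAP1,down
ANK3,down
BSPRY,down
CD24,down
CDH1,down
CLDN3,down
CLDN4,down
CTTN,down
EFNA4,down
ELF3,down
EPN3,down
FLNB,down
FXYD3,down
GAS2L1,down
GCAT,down
GPR56,down
H1F0,down
HIST1H2BD,down
HIST2H2BE,down
KRT18,down
KRT19,down
KRT8,down
LASS2,down
MB,down
MTA1,down
MYO6,down
NEBL,down
PBX1,down
PIK3R3,down
PPM1H,down
PTPRF,down
SLC19A2,down
TOB1,down
TOM1L1,down
TPD52,down
TPD52L1,down
TRAF4,down
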