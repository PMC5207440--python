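cell_line,declared_subtype,ER,PR,HER2,CK5,EGFR,CLDN3,CLDN4,CLDN7,ECAD,CD24
MCF7,luminal,7,5,0,0,0,7,7,8,6,0
ZR751,luminal,7,4,5,0,0,3,3,7,8,0
SKBR3,luminal-her2amp,0,0,8,0,6,3,6,7,0,0
BT474,luminal-her2amp,7,4,8,0,4,8,8,8,6,0
MDAMB361,luminal-her2amp,4,0,8,0,4,8,7,8,7,0
BT20,basal,0,0,0,7,8,0,5,7,6,0
HCC1954,basal-her2amp,0,0,8,8,8,0,8,8,8,0
BT549,claudin-low,0,0,0,0,7,0,0,0,0,0
MDAMB231,claudin-low,0,0,0,0,8,0,3,0,0,0
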