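DUSP4
DUSP6
ELF1
ETV4
ETV5
FXYD5
KANK1
LGALS3
LZTS1
MAP2K3
PHLDA1
PROS1
S100A6
SERPINB1
SLCO4A
SPRY2
TRIB2
ZFP106
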