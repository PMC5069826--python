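BIRC6
EMC8
HADHA
MAEA
MRPL18
ORMDL1
PSMD11
RBM4
STX6
TRIM39
UBE2K
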