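# Known Alzheimer's disease genes and GWAS-implicated loci (editable).
# Early-onset genes plus the late-onset loci reported in the tier-1 table.
APP
PSEN1
PSEN2
GRN
TREM2
AKAP9
CD33
CR1
EPHA1
INPP5D
NME8
SORL1
UNC5C
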