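# Cancer-predisposition genes from the ACMG secondary-findings list (SF v2.0).
# Editable: the SF list is versioned; replace or extend as needed.
APC
BMPR1A
BRCA1
BRCA2
MEN1
MLH1
MSH2
MSH6
MUTYH
NF2
PMS2
PTEN
RB1
RET
SDHAF2
SDHB
SDHC
SDHD
SMAD4
STK11
TP53
TSC1
TSC2
VHL
WT1
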