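# Cardiovascular-disease genes from the ACMG secondary-findings list (SF v2.0).
# Editable: the SF list is versioned; replace or extend as needed.
ACTA2
ACTC1
APOB
COL3A1
DSC2
DSG2
DSP
FBN1
KCNH2
KCNQ1
LDLR
LMNA
MYBPC3
MYH11
MYH7
MYL2
MYL3
PCSK9
PKP2
PRKAG2
RYR2
SCN5A
SMAD3
TGFBR1
TGFBR2
TMEM43
TNNI3
TNNT2
TPM1
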