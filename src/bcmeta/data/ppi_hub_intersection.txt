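IL6
VEGFA
CCNB1
BRCA1
CCNA2
CD44
TYMS
AURKB
EZH2
MKI67
KIF23
ECT2
MCM4
CDC6
PLK1
CDC25C
CDKN3
CENPA
TOP2A
CENPE
PBK
NDC80
FOXM1
SPP1
IGF1
UBE2C
RRM2
KIF11
CHEK1
CD8A
CCNB2
ASPM
NCAM1
DLGAP5
CDCA8
CDC20
BUB1
KIF20A
EXO1
CDC25A
VCL
LUM
CD34
MCM2
MAD2L1
NCAPG
CENPU
HJURP
CCL2
TPM1
PLK4
GJA1
PTGS2
ANXA5
COL6A1
TRIP13
OIP5
MYH11
TTK
MYL9
CAV1
FBXO5
PROM1
BMP4
CDT1
KIAA0101
ATAD2
ESPL1
NT5E
ZWINT
SDC1
FGF2
NEK2
ACTG2
KIF14
COL3A1
ASF1B
RAD54L
COL4A5
CASC5
CENPM
CDC45
TACC3
MYLK
GINS2
CENPF
TGFBR2
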