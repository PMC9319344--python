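IL6
VEGFA
CCNB1
BRCA1
CCNA2
CD44
TYMS
CDH1
LMNB1
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
MMP2
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
FLNA
LGALS4
ITPR1
DLGAP5
CDCA8
COL5A1
TIMELESS
CDC20
DMD
PPARGC1A
WNT5A
BUB1
KIF20A
EXO1
CDC25A
VCL
LUM
CCND2
CD34
MCM2
MAD2L1
HPGDS
ISL1
ESRP1
SKP2
NCAPG
CENPU
HJURP
CCL2
TPM1
CDH11
PLK4
FABP4
H2AFX
GJA1
DHCR7
PTGS2
MSN
ANXA5
COL6A1
TRIP13
OIP5
MYH11
KRT20
TTK
MYL9
CAV1
FBXO5
PROM1
BMP4
CDT1
KIAA0101
CCNE1
ANXA1
FGFR3
SNCA
ATAD2
ESPL1
FASN
NT5E
ZWINT
SDC1
FGF2
NEK2
ACTG2
KIF14
COL3A1
EPCAM
ASF1B
IGFBP5
RAD54L
CYP1B1
STMN1
COL4A5
ATF3
CASC5
CENPM
ERBB3
DNMT3B
ITGB2
ISG15
ANK2
CDC45
PLAT
TACC3
EGR1
MYLK
CTSG
GINS2
ITGA8
CENPF
TGFBR2
OGN
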