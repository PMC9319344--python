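module	genes
turquoise	ACTG2,ANXA5,AURKB,BUB1,CD34,CD44,CDC25A,CDT1,CENPM,ESPL1,EXO1,FGF2,GINS2,KIF20A,NCAM1
brown	CAV1,COL3A1,COL4A5,IGF1,LUM,MYLK,PROM1,SDC1,SPP1,TPM1,VCL,VEGFA
black	ASPM,CCNA2,CCNB1,CCNB2,CDC20,CDC45,CDCA8,CDKN3,CENPA,CENPF,CENPU,DLGAP5,ECT2,EZH2,FOXM1,HJURP,KIF11,KIF14,KIF23,MCM2,MCM4,MKI67,NCAPG,NDC80,NEK2,PBK,PLK4,RAD54L,TOP2A,TTK,UBE2C,ZWINT
blue	
green	COL6A1,MYH11
yellow	
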