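cluster	score	n_nodes	genes
1	74.268	83	PLK4,TRIP13,CDC45,PBK,RRM2,ERCC6L,CHAF1A,DEPDC1,DLGAP5,ASPM,E2F8,MAD2L1,CDCA8,CCNB1,BRCA1,FANCI,FBXO5,CENPA,KIAA0101,TK1,TACC3,DTL,CDCA3,HJURP,CENPE,ZWINT,ESPL1,POLQ,OIP5,CDC25C,ASF1B,CDKN3,POLE2,CCNB2,CHAF1B,EZH2,UBE2C,RAD54L,CDT1,MCM5,CDC20,TROAP,CKS2,NEK2,SPC25,MKI67,CHEK1,TTK,CDC6,GINS2,BUB1,CENPU,CCNE2,STIL,KIF14,TYMS,CDC7,MCM2,KIF23,KNTC1,SKA1,CASC5,CENPF,HELLS,NUSAP1,ATAD2,CEP55,NCAPG,MCM4,NDC80,ECT2,TOP2A,CENPM,CDC25A,MCM10,ORC1,KIF20A,AURKB,CCNA2,PLK1,EXO1,FOXM1,KIF11
2	18	23	CXCL12,PTGS2,BMP4,IL6,GJA1,CD34,FGF2,NES,PROM1,CD8A,VEGFA,CD44,SDC1,SPP1,ANXA5,NCAM1,SELP,CCL2,CCL5,IGF1,CSF1R,NT5E,SELE
3	7.923	27	TGFBI,COL6A2,THBS2,TPM1,MYH11,ACTG2,COL6A1,COL13A1,COL3A1,TGFBR2,VCL,FBLN2,COL4A5,CTSK,LYVE1,CLDN5,ANGPT2,LUM,MYL9,LEPREL1,TPM2,SPARC,MYLK,CAV1,ADAMTS5,TAGLN,FMOD
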