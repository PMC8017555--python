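locus	cv_count	target_genes
1p34.3	5	RP11-109P14.10,MTF1,INPP5B,GNL2,LINC01137,ZC3H12A
2q31.1	17	LINC01116,LINC01117,HOXD1,AC079305.8,MIR4444-2,HNRNPA3
3q25.31	54	PLCH1,AC104472.1,C3orf33,SSR3,TIPARP,TIPARP-AS1,LEKR1,LINC00880,RP11-6F2.5,LINC00881,CCNL1,RNA5SP146,RP11-550I24.2,LINC00886,PA2G4P4
5p15.33	1	TRIP13
8q24.21	32	CASC8,CASC11,RP11-419K12.1,RP11-89M16.1,MYC,PVT1
9p22.2	11	BNC2
9q34.2	35	ABO,RP11-430N14.4,RALGDS,SURF4,C9orf96,REXO4,ADAMTS13
10p12.31	5	RP11-275N1.1,NEBL-AS1,NEBL,MLLT10
15q26.1	28	RN7SL346P,SEMA4B,RP11-154B12.3,IQGAP1,HDDC3,RP11-387D10.2,RP11-387D10.3,UNC45A,AC068831.3,RCCD1,AC068831.6,VPS33B,AC068831.10,PRC1,PRC1-AS1,AC068831.11,AC068831.12,RP11-661P17.1,CTD-2313J17.1,FAM174B
17q12	10	GGNBP2,DHRS11,SYNRG,DDX52,RP11-697E22.1,RP11-697E22.2,RP11-697E22.3,HNF1B,YWHAEP7,AC124789.1,ARHGAP23
17q21.31	244	AC002117.1,HEXIM2,CTD-2020K17.1,FMNL1,DND1P1,RP11-259G18.1,KANSL1,NSF,WNT3,ARL17B
17q21.32	96	SKAP1,RP11-456D7.1,RNU6-1152P,HOXB3,HOXB-AS3,HOXB-AS2,HOXB4,MIR10A,HOXB7,HOXB8,HOXB9,HOXB6,HOXB5,HOXB2,HOXB-AS1,Y_RNA,COPZ2,CBX1,SNX11,MIR1203,RP11-357H14.17,RP11-433M22.2,HOXB-AS4,MIR196A1
19p13.11	15	CTC-429P9.4,SMIM7,TMEM38A,HAUS8,MYO9B,USE1,OCEL1,NR2F6,AC010646.3,USHBP1,ANO8,GTPBP3,CTD-3131K8.2,PGLS,ABHD8,DDA1,PLVAP,CTD-2521M24.9,BST2,MVB12A,CTD-2521M24.6,CTD-2521M24.8,CTD-2521M24.5
22q12.1	96	PITPNB,TTC28-AS1,MIR3199-2,TTC28,CHEK2,CCDC117,CTA-292E10.6,XBP1,HSCB,RN7SL162P,ZNRF3-AS1,ZNRF3,RHBDD3,EWSR1,MIAT,CTA-373H7.7,CTA-211A9.5,CTA-292E10.7
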