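cluster_id	class	members
R01	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,FMR1_iso7,FXR2,LIN28A,LIN28B,MOV10,TIA1,TIAL1,ZC3H7B
R02	RBP	AGO1,AGO2,ELAVL1,IGF2BP1,IGF2BP2,IGF2BP3,TIAL1
R03	Singleton	AGO1
R04	RBP	ELAVL1,HNRNPD
R05	RBP	AGO1,AGO2,ELAVL1,EWSR1,FMR1_iso1,FUS,LIN28A,LIN28B,TAF15,TIA1,TIAL1,ZC3H7B
R06	RBP	AGO1,ELAVL1,TIA1,TIAL1
R07	RBP	AGO1,FMR1_iso1,FMR1_iso7
R08	RBP	AGO1,AGO2,CAPRIN1,ELAVL1,FMR1_iso1,FMR1_iso7,LIN28B,TIA1,TIAL1,ZC3H7B
R09	RBP	AGO1,AGO2,C22ORF28,ELAVL1,FMR1_iso1,FMR1_iso7,LIN28B,TIA1,TIAL1,ZC3H7B
R10	RBP-miRNA	LIN28A,LIN28B,hsa-miR-221*
R11	RBP	AGO1,HNRNPH
R12	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,HNRNPC,TIA1,TIAL1
R13	Singleton	PUM1
R14	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,FMR1_iso7,HNRNPU,TIA1,TIAL1
R15	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,FMR1_iso7,HNRNPF,TIA1,TIAL1
R16	RBP	AGO1,AGO2,ELAVL1,EWSR1,FMR1_iso1,FMR1_iso7,FXR1,FXR2,LIN28A,LIN28B,TIA1,TIAL1,ZC3H7B
R17	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,IGF2BP1,IGF2BP2,IGF2BP3,PUM2,TIA1,TIAL1
R18	Singleton	PABPC1
R19	Singleton	U2AF2
R20	RBP-miRNA	AGO1,AGO2,ELAVL1,FMR1_iso1,IGF2BP1,IGF2BP2,IGF2BP3,TIA1,TIAL1,hsa-miR-130a,hsa-miR-130b,hsa-miR-148a,hsa-miR-148b,hsa-miR-301a,hsa-miR-301b
R21	RBP-miRNA	AGO1,AGO2,ELAVL1,FMR1_iso1,IGF2BP1,IGF2BP2,IGF2BP3,TIA1,TIAL1,hsa-miR-15a,hsa-miR-15b,hsa-miR-16,hsa-miR-424
R22	Singleton	DGCR8
R23	RBP-miRNA	AGO1,AGO2,ELAVL1,FMR1_iso1,IGF2BP1,IGF2BP2,IGF2BP3,TIA1,TIAL1,hsa-miR-106b,hsa-miR-17,hsa-miR-20a,hsa-miR-320,hsa-miR-93
R24	RBP-miRNA	AGO1,AGO2,ELAVL1,IGF2BP1,IGF2BP2,IGF2BP3,TIAL1,hsa-let-7a,hsa-let-7b,hsa-let-7c,hsa-let-7d,hsa-let-7e,hsa-let-7f,hsa-let-7g,hsa-let-7i
R25	RBP	AGO1,AGO2,ELAVL1,FMR1_iso1,HNRNPA2B1,TIA1,TIAL1
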