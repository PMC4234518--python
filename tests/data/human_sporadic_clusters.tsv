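cluster_id	class	members
S01	Singleton	HNRNPD
S02	RBP	CAPRIN1,FUS,FXR1,MOV10,TAF15
S03	Singleton	HNRNPH
S04	RBP	C22ORF28,CAPRIN1,MOV10
S05	Singleton	HNRNPC
S06	Singleton	HNRNPU
S07	Singleton	HNRNPF
S08	Singleton	PUM1
S09	miRNA	hsa-miR-15a,hsa-miR-15b,hsa-miR-16,hsa-miR-424
S10	RBP-miRNA	PUM2,hsa-miR-130a,hsa-miR-130b,hsa-miR-148a,hsa-miR-148b,hsa-miR-19a,hsa-miR-19b,hsa-miR-301a,hsa-miR-301b
S11	Singleton	HNRNPA2B1
S12	Singleton	PABPC1
S13	Singleton	U2AF2
S14	miRNA	hsa-miR-106b,hsa-miR-17,hsa-miR-20a,hsa-miR-93
S15	RBP	MOV10,PUM2
S16	miRNA	hsa-let-7a,hsa-let-7b,hsa-let-7c,hsa-let-7d,hsa-let-7e,hsa-let-7f,hsa-let-7g,hsa-let-7i
S17	Singleton	DGCR8
S18	Singleton	C17ORF85
S19	Singleton	TARDBP
S20	RBP	FUS,MOV10,TAF15
S21	RBP-miRNA	PUM2,hsa-miR-103,hsa-miR-107,hsa-miR-183,hsa-miR-221,hsa-miR-222,hsa-miR-23b,hsa-miR-25,hsa-miR-27a,hsa-miR-27b,hsa-miR-32,hsa-miR-92a,hsa-miR-96
S22	miRNA	hsa-miR-103,hsa-miR-107,hsa-miR-15a,hsa-miR-15b,hsa-miR-16,hsa-miR-29a,hsa-miR-29b,hsa-miR-29c,hsa-miR-424
S23	Singleton	CELF1
S24	Singleton	hsa-miR-124
S25	Singleton	hsa-miR-1
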