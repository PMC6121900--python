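accession	modification	position	window	sources	pubmed_ids	asa
O00194	N-acetylthreonine	2	MTDGDY			
O43592	N-acetylmelthionine	1	MDEQA			
O43592	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	557	KSLNKQMNP			
O43592	N6-acetyllysine	627	PLMEKFKIL			
O43592	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	629	MEKFKILLE			
O43592	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	634	ILLEKLMLA			
O43592	N6-acetyllysine	634	ILLEKLMLA			
O43592	Phosphothreonine	661	FASRTSKAF			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	39	SWDNCDEGK			
P17900	N-linked (GlcNAc)	63	IVPGNVTLS			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	99	IKIPCTDYI			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	106	YIGSCTFEH			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	112	FEHFCDVLD			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	125	TGEPCPEPL			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	136	YGLPCHCPF			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	138	LPCHCPFKE			
P17900	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	183	KRLGCIKIA			
P07996	N-linked (GlcNAc)	248	NNVVNGSSP			
P07996	C-linked (Man)	385	GWSPWSEWT			
P07996	O-linked (Fuc)	394	SCSTSCGNG			
P07996	O-linked (GalNAc)	394	SCSTSCGNG			
P07996	C-linked (Man)	438	QDGGWSHWS			
P07996	C-linked (Man)	441	GWSHWSPWS			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	447	PWSSCSVTC			
P07996	O-linked (Fuc)	450	SCSVTCGDG			
P07996	O-linked (GalNAc)	450	SCSVTCGDG			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	451	CSVTCGDGV			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	462	RIRLCNSPS			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	474	NGKPCEGEA			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	484	ETKACKKDA			
P07996	S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)	489	KKDACPING			
P07996	C-linked (Man)	498	GWGPWSPWD			
P07996	O-linked (Fuc)	507	ICSVTCGGG			
P07996	N-linked (GlcNAc)	1067	VKVVNSTTG			
P25786	N-acetylmethionine	1	MFRNQ			
P25786	Phosphoserine	14	VTVWSPQGR			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	30	MEAVKQGSA			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	39	YTVGLKSKTH			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	51	GLKSKTHAV			
P25786	Phosphoserine	54	KRAQSELAA			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	61	AAHQKKILH			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	115	LIGSKTQIP			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	208	DLTTKNVSI			
P25786	Phosphoserine	211	TKNVSIGIV			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	243	RPQRKAQPA			
P25786	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	256	EPAEKADEP			
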