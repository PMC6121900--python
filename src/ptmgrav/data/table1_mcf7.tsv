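gene	protein_name	accession	lfq_1g	lfq_ug
RAB27B	Ras-related protein Rab-27B	O00194	7.24	22.81
XPOT	Exportin-T	O43592	6.62	12.92
NMT2	Glycylpeptide N-tetradecanoyltransferase 2	O60551	0.39	0.72
FUCA1	Tissue alpha-l-fucosidase	P04066	5.32	9.95
THBS1	Thrombospondin-1	P07996	3.89	11.10
IGFBP2	Insulin-like growth factor-binding protein 2	P18065	0.92	1.85
CBL	E3 ubiquitin-protein ligase CBL	P22681	0.12	0.23
UBE2D1	Ubiquitin-conjugating enzyme E2 D1	P51668	0.00	1.14
USP11	Ubiquitin carboxyl-terminal hydrolase 11	P51784	0.27	0.56
BLOC1S1	Biogenesis of lysosome-related organelles complex 1 subunit 1	P78537	0.82	2.45
GALK2	N-acetylgalactosamine kinase	Q01415	2.10	4.82
TP53I3	Quinone oxidoreductase PIG3	Q53FA7	0.41	0.77
ZFYVE26	Zinc finger FYVE domain-containing protein 26	Q68DK2	0.05	0.16
C3orf17	Uncharacterized protein C3orf17	Q6NW34	0.05	0.25
FASTKD5	FAST kinase domain-containing protein 5	Q7L8L6	0.00	0.46
HS2ST1	Heparan sulfate 2-O-sulfotransferase 1	Q7LGA3	0.00	0.37
SZRD1	SUZ domain-containing protein 1	Q7Z422	0.00	0.24
UBE2Q1	Ubiquitin-conjugating enzyme E2 Q1	Q7Z7E8	1.21	2.94
SYVN1	E3 ubiquitin-protein ligase synoviolin	Q86TM6	1.09	4.39
SLC35B2	Adenosine 3-phospho 5-phosphosulfate transporter 1	Q8TB61	3.97	7.42
NEK9	Serine/threonine-protein kinase Nek9	Q8TD19	0.86	1.75
CHMP7	Charged multivesicular body protein 7	Q8WUX9	0.99	1.92
GTF3C6	General transcription factor 3C polypeptide 6	Q969F1	1.37	2.79
AIDA	Axin interactor. dorsalization-associated protein	Q96BJ3	0.00	0.17
GPATCH1	G patch domain-containing protein 1	Q9BRR8	0.00	0.13
ADI1	1.2-dihydroxy-3-keto-5-methylthiopentene dioxygenase	Q9BV57	16.08	29.15
DUSP23	Dual specificity protein phosphatase 23	Q9BVJ7	2.76	5.02
C20orf27	UPF0687 protein C20orf27	Q9GZN8	2.55	5.08
DNAJC5	DnaJ homolog subfamily C member 5	Q9H3Z4	7.88	14.60
CBX8	Chromobox protein homolog 8	Q9HC52	1.79	3.86
BIN3	Bridging integrator 3	Q9NQY0	0.00	0.27
TBC1D13	TBC1 domain family member 13	Q9NVG8	1.59	2.98
IGBP1	Immunoglobulin-binding protein 1	P78318	1.14	2.33
ANKRD52	Serine/threonine-protein phosphatase 6 regulatory ankyrin repeat subunit C	Q8NB46	0.00	0.18
THOP1	Thimet oligopeptidase	P52888	1.58	3.49
AGPAT9	Glycerol-3-phosphate acyltransferase 3	Q53EU6	0.00	0.13
HBA2	Hemoglobin subunit alpha	G3V1N2	2.05	5.25
UBE2D3	Ubiquitin-conjugating enzyme E2 D3	P61077	0.00	2.26
GM2A	Ganglioside GM2 activator	P48637	1.12	2.45
KDM2A	Lysine-specific demethylase 2A	Q9Y2K7	1.47	4.13
GSS	Glutathione synthetase	P48637	2.14	4.99
TMEM263	Transmembrane protein 263	Q8WUH6	3.66	9.68
BRD2	Bromodomain-containing protein 2	P25440	5.15	9.39
GCLM	Glutamate-cysteine ligase regulatory subunit	P48507	0.30	1.93
PPP5C	Serine/threonine-protein phosphatase 5	P53041	3.96	7.77
PTGR1	Prostaglandin reductase 1	Q14914	1.21	5.62
PIN4	Peptidyl-prolyl cis-trans isomerase NIMA-interacting 4	Q9Y237	5.64	10.88
TXNDC17	Thioredoxin domain-containing protein 17	Q9BRA2	14.38	52.39
PSMB3	Proteasome subunit beta type-3	P49720	1.05	2.50
HSP90AB2P	Putative heat shock protein HSP 90-beta 2	Q58FF8	9.79	36.46
DDT	D-dopachrome decarboxylase	P30046	1.35	5.21
OSTF1	Osteoclast-stimulating factor 1	Q92882	2.97	7.56
UFM1	Ubiquitin-fold modifier 1	P61960	12.82	25.55
APOB	Apolipoprotein B-100	P04114	0.10	10.18
CRABP2	Cellular retinoic acid-binding protein 2	P29373	13.46	65.46
PSMA1	Proteasome subunit alpha type-1	P25786	5.40	10.70
HMOX1	Heme oxygenase 1	P09601	0.58	1.39
COPB1	Coatomer subunit beta	P53618	83.81	122.10
CKB	Creatine kinase B-type	P12277	0.72	1.35
NQO1	NAD(P)H dehydrogenase [quinone] 1	P15559	65.66	183.60
PSMA6	Proteasome subunit alpha type-6	P60900	2.53	8.56
TPT1	Translationally-controlled tumor protein	P13693	13.01	35.49
DSTN	Destrin	P60981	7.27	34.58
TXN	Thioredoxin	P10599	209.20	431.80
COPB2	Coatomer subunit beta	P35606	57.34	107.40
STIP1	Stress-induced-phosphoprotein 1	P31948	123.00	208.20
PFN1	Profilin-1	P07737	126.10	265.10
NSF	Vesicle-fusing ATPase	P46459	41.33	76.30
CFL1	Cofilin-1	P23528	238.90	628.90
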