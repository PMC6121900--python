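gene	protein_name	accession	lfq_1g	lfq_ug
RAB27B	Ras-related protein Rab-27B	O00194	0.00	1.11
XPOT	Exportin-T	O43592	0.00	1.75
NMT2	Glycylpeptide N-tetradecanoyltransferase 2	O60551	0.00	0.31
FUCA1	Tissue alpha-l-fucosidase	P04066	0.00	1.02
THBS1	Thrombospondin-1	P07996	0.00	3.96
IGFBP2	Insulin-like growth factor-binding protein 2	P18065	0.00	7.25
CBL	E3 ubiquitin-protein ligase CBL	P22681	0.00	0.74
UBE2D1	Ubiquitin-conjugating enzyme E2 D1	P51668	0.00	0.49
USP11	Ubiquitin carboxyl-terminal hydrolase 11	P51784	0.00	0.98
BLOC1S1	Biogenesis of lysosome-related organelles complex 1 subunit 1	P78537	0.00	0.60
GALK2	N-acetylgalactosamine kinase	Q01415	0.00	0.61
TP53I3	Quinone oxidoreductase PIG3	Q53FA7	0.00	1.52
ZFYVE26	Zinc finger FYVE domain-containing protein 26	Q68DK2	0.00	0.22
C3orf17	Uncharacterized protein C3orf17	Q6NW34	0.00	1.01
FASTKD5	FAST kinase domain-containing protein 5	Q7L8L6	0.00	1.02
HS2ST1	Heparan sulfate 2-O-sulfotransferase 1	Q7LGA3	0.00	3.13
SZRD1	SUZ domain-containing protein 1	Q7Z422	0.00	3.52
UBE2Q1	Ubiquitin-conjugating enzyme E2 Q1	Q7Z7E8	0.00	1.64
SYVN1	E3 ubiquitin-protein ligase synoviolin	Q86TM6	0.00	0.69
SLC35B2	Adenosine 3-phospho 5-phosphosulfate transporter 1	Q8TB61	0.00	6.82
NEK9	Serine/threonine-protein kinase Nek9	Q8TD19	0.00	1.38
CHMP7	Charged multivesicular body protein 7	Q8WUX9	0.00	0.98
GTF3C6	General transcription factor 3C polypeptide 6	Q969F1	0.00	0.97
AIDA	Axin interactor. dorsalization-associated protein	Q96BJ3	0.00	1.91
GPATCH1	G patch domain-containing protein 1	Q9BRR8	0.00	0.77
ADI1	1.2-dihydroxy-3-keto-5-methylthiopentene dioxygenase	Q9BV57	0.00	1.32
DUSP23	Dual specificity protein phosphatase 23	Q9BVJ7	0.00	1.75
C20orf27	UPF0687 protein C20orf27	Q9GZN8	0.00	1.05
DNAJC5	DnaJ homolog subfamily C member 5	Q9H3Z4	0.00	1.84
CBX8	Chromobox protein homolog 8	Q9HC52	0.00	3.35
BIN3	Bridging integrator 3	Q9NQY0	0.00	1.34
TBC1D13	TBC1 domain family member 13	Q9NVG8	0.00	1.60
IGBP1	Immunoglobulin-binding protein 1	P78318	0.70	1.32
ANKRD52	Serine/threonine-protein phosphatase 6 regulatory ankyrin repeat subunit C	Q8NB46	0.73	1.37
THOP1	Thimet oligopeptidase	P52888	1.04	2.05
AGPAT9	Glycerol-3-phosphate acyltransferase 3	Q53EU6	1.25	2.46
HBA2	Hemoglobin subunit alpha	G3V1N2	1.43	8.92
UBE2D3	Ubiquitin-conjugating enzyme E2 D3	P61077	1.60	4.05
GM2A	Ganglioside GM2 activator	P48637	1.75	3.34
KDM2A	Lysine-specific demethylase 2A	Q9Y2K7	1.87	5.59
GSS	Glutathione synthetase	P48637	1.89	5.08
TMEM263	Transmembrane protein 263	Q8WUH6	2.29	4.19
BRD2	Bromodomain-containing protein 2	P25440	2.33	4.43
GCLM	Glutamate-cysteine ligase regulatory subunit	P48507	3.91	9.31
PPP5C	Serine/threonine-protein phosphatase 5	P53041	3.99	9.22
PTGR1	Prostaglandin reductase 1	Q14914	5.25	11.92
PIN4	Peptidyl-prolyl cis-trans isomerase NIMA-interacting 4	Q9Y237	5.59	12.75
TXNDC17	Thioredoxin domain-containing protein 17	Q9BRA2	5.88	14.58
PSMB3	Proteasome subunit beta type-3	P49720	5.92	10.72
HSP90AB2P	Putative heat shock protein HSP 90-beta 2	Q58FF8	6.19	13.49
DDT	D-dopachrome decarboxylase	P30046	6.46	13.31
OSTF1	Osteoclast-stimulating factor 1	Q92882	7.47	19.57
UFM1	Ubiquitin-fold modifier 1	P61960	7.89	15.94
APOB	Apolipoprotein B-100	P04114	8.67	49.51
CRABP2	Cellular retinoic acid-binding protein 2	P29373	8.88	17.32
PSMA1	Proteasome subunit alpha type-1	P25786	13.84	27.82
HMOX1	Heme oxygenase 1	P09601	14.62	108.19
COPB1	Coatomer subunit beta	P53618	16.30	37.00
CKB	Creatine kinase B-type	P12277	21.21	40.30
NQO1	NAD(P)H dehydrogenase [quinone] 1	P15559	22.76	56.44
PSMA6	Proteasome subunit alpha type-6	P60900	23.40	47.27
TPT1	Translationally-controlled tumor protein	P13693	26.04	64.58
DSTN	Destrin	P60981	27.10	79.13
TXN	Thioredoxin	P10599	34.20	88.24
COPB2	Coatomer subunit beta	P35606	55.33	102.36
STIP1	Stress-induced-phosphoprotein 1	P31948	80.66	186.81
PFN1	Profilin-1	P07737	89.96	221.30
NSF	Vesicle-fusing ATPase	P46459	93.46	206.55
CFL1	Cofilin-1	P23528	150.60	316.26
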