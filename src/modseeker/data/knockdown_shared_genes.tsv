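gene	gene_name	sw480_p	sw480_q	sw480_log2fc	caco2_p	caco2_q	caco2_log2fc
AURKA	Aurora kinase A	1.69e-6	1.86e-2	-1.64	2.28e-7	1.96e-3	-1.31
REEP5	Receptor accessory protein 5	2.20e-5	1.86e-2	-1.24	1.83e-6	5.18e-3	-0.97
SLC12A2	Solute carrier family 12 member 2	5.70e-6	1.86e-2	-1.05	1.39e-5	6.82e-3	0.70
DICER1	Dicer 1, ribonuclease III	1.94e-4	2.35e-2	-1.02	6.79e-5	1.00e-2	-0.75
FEZ2	Fasciculation and elongation protein zeta 2	7.41e-6	1.86e-2	-0.99	7.61e-6	6.82e-3	-0.70
KRAS	KRAS proto-oncogene, GTPase	9.58e-6	1.86e-2	-0.95	1.10e-5	6.82e-3	-0.65
UBE2D1	Ubiquitin conjugating enzyme E2 D1	3.08e-4	2.55e-2	-0.92	1.08e-5	6.82e-3	-0.91
TM4SF1	Transmembrane 4 L six family member 1	1.10e-4	2.28e-2	-0.91	2.03e-5	7.98e-3	-0.74
ACVR1	Activin A receptor type 1	2.60e-4	2.46e-2	-0.87	6.36e-6	6.82e-3	-0.99
MARVELD2	MARVEL domain containing 2	2.61e-5	1.86e-2	-0.87	2.13e-5	7.98e-3	-0.66
BORCS8	BLOC-1-related complex subunit 8	2.91e-5	1.86e-2	-0.86	1.61e-5	7.31e-3	-0.64
SLC25A24	Solute carrier family 25 member 24	5.87e-5	2.10e-2	-0.85	1.10e-5	6.82e-3	-0.71
MBOAT2	Membrane bound O-acyltransferase domain containing 2	1.73e-4	2.35e-2	-0.76	7.00e-6	6.82e-3	-0.84
ACOX2	Acyl-CoA oxidase 2	3.59e-5	1.86e-2	-0.74	2.78e-5	8.77e-3	-0.61
TNFRSF11B	TNF receptor superfamily member 11b	3.13e-5	1.86e-2	-0.74	3.02e-7	1.96e-3	-1.18
ENSG00000260912	ENSG00000260912	3.47e-3	4.91e-2	-0.74	4.04e-5	9.30e-3	-1.05
ENSG00000234119	ENSG00000234119	3.74e-5	1.91e-2	-0.71	8.20e-6	6.82e-3	-0.69
SNX24	Sorting nexin 24	2.46e-3	4.32e-2	-0.70	5.16e-5	9.83e-3	-0.86
ANP32A	Acidic nuclear phosphoprotein 32 family member A	8.22e-5	2.26e-2	-0.70	2.15e-5	7.98e-3	-0.62
CANX	Calnexin	5.44e-4	2.89e-2	-0.70	2.32e-6	5.52e-3	-0.95
TMX2P1	Thioredoxin related transmembrane protein 2 pseudogene 1	2.87e-4	2.49e-2	-0.70	5.42e-5	9.96e-3	-0.63
B4GALT4	Beta-1,4-galactosyltransferase 4	8.17e-4	3.19e-2	-0.68	3.53e-6	6.82e-3	-1.17
SNX4	Sorting nexin 4	1.09e-4	2.28e-2	-0.67	4.74e-5	9.65e-3	-0.61
TSPYL4	TSPY like 4	1.41e-4	2.35e-2	-0.66	8.55e-6	6.82e-3	-0.71
PHLDA2	Pleckstrin homology like domain family A member 2	1.67e-3	3.74e-2	-0.60	4.19e-5	9.37e-3	-0.61
TP53I3	Tumor protein p53 inducible protein 3	1.31e-4	2.35e-2	-0.59	2.61e-5	8.77e-3	-0.60
ARHGAP19	Rho GTPase activating protein 19	2.25e-4	2.37e-2	0.59	7.93e-6	6.82e-3	0.74
LAMC1	Laminin subunit gamma 1	6.03e-4	2.95e-2	0.60	6.01e-6	6.82e-3	0.96
STK17B	Serine/threonine kinase 17b	1.32e-3	3.54e-2	0.61	5.71e-5	1.00e-2	0.65
NRP2	Neuropilin 2	2.83e-3	4.55e-2	0.65	4.83e-5	9.65e-3	0.85
IDNK	IDNK, gluconokinase	2.18e-3	4.17e-2	0.67	2.16e-4	1.34e-2	0.62
KTN1	Kinetin 1	4.50e-5	2.05e-2	0.68	1.88e-5	7.93e-3	0.60
RACGAP1	Rac GTPase activating protein 1	2.77e-4	2.49e-2	0.72	6.11e-5	1.00e-2	0.65
CDK6	Cyclin dependent kinase 6	8.63e-5	2.26e-2	0.75	4.60e-6	6.82e-3	0.86
SPA17	Sperm autoantigenic protein 17	1.51e-4	2.35e-2	0.77	2.00e-5	7.98e-3	0.66
LINC00467	Long intergenic non-protein coding RNA 467	3.30e-5	1.86e-2	0.80	8.62e-6	6.82e-3	0.68
BUB1B	BUB1 mitotic checkpoint serine/threonine kinase B	3.99e-5	1.94e-2	0.83	1.84e-5	7.89e-3	0.70
BIK	BCL2 interacting killer	3.11e-5	1.86e-2	0.86	2.01e-6	5.18e-3	0.87
SH3D19	SH3 domain containing 19	1.22e-4	2.35e-2	0.89	1.05e-5	6.82e-3	0.83
EIF4EBP2	Eukaryotic translation initiation factor 4E binding protein 2	7.50e-5	2.26e-2	0.92	2.09e-5	7.98e-3	0.72
HMMR	Hyaluronan mediated motility receptor	4.07e-5	1.95e-2	0.95	1.17e-5	6.82e-3	0.74
KLHL15	Kelch like family member 15	3.55e-4	2.64e-2	0.95	2.46e-4	1.42e-2	0.59
DYRK2	Dual specificity tyrosine phosphorylation regulated kinase 2	4.09e-4	2.69e-2	0.97	3.68e-5	9.30e-3	0.80
ZNF268	Zinc finger protein 268	3.95e-4	2.66e-2	0.98	8.72e-5	1.07e-2	0.67
NUP98	Nucleoporin 98	9.71e-6	1.86e-2	0.98	6.76e-6	6.82e-3	0.73
MTMR6	Myotubularin related protein 6	8.09e-4	3.19e-2	0.99	1.18e-4	1.20e-2	0.78
PTP4A1	Protein tyrosine phosphatase type IVA, member 1	5.08e-4	2.85e-2	1.04	1.94e-4	1.31e-2	0.80
GOLT1B	Golgi transport 1B	1.36e-5	1.86e-2	1.04	1.95e-5	7.98e-3	0.63
RPS27L	Ribosomal protein S27 like	6.91e-6	1.86e-2	1.05	1.06e-5	6.82e-3	0.67
MALAT1	Metastasis associated lung adenocarcinoma transcript 1	1.46e-3	3.66e-2	1.09	1.06e-5	6.82e-3	1.67
LAMP2	Lysosomal associated membrane protein 2	3.30e-4	2.62e-2	1.10	4.75e-5	9.65e-3	0.98
SYPL1	Synaptophysin like 1	5.69e-6	1.86e-2	1.11	5.63e-6	6.82e-3	0.73
ARRDC4	Arrestin domain containing 4	1.55e-3	3.70e-2	1.24	2.11e-3	3.15e-2	0.64
MBNL1	Muscleblind like splicing regulator 1	1.73e-6	1.86e-2	1.34	5.91e-6	6.82e-3	0.73
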