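protein_name	agi_locus	mw_kda	cycling	LNK1-HFC_ZT9_1	LNK1-HFC_ZT9_2	LNK2-HFC_ZT9_1	LNK2-HFC_ZT9_2	RVE8-HFC_ZT9_1	RVE8-HFC_ZT9_2
LNK1	AT5G64170	70	1	435	621	0	0	66	90
LNK2	AT3G54500	81	1	0	0	140	151	109	137
RVE8	AT3G09600	40	1	71	101	33	52	285	317
RVE6	AT5G52660	36	0	86	113	21	22	4	3
RVE5	AT4G01280	34	1	32	51	12	12	0	0
TCF1	AT3G55580	51	1	32	49	20	30	13	13
RVE4	AT5G02840	31	1	31	43	0	7	0	0
RCC1L	AT3G53830	49	1	20	25	3	10	0	0
COR28	AT4G33980	26	1	11	15	6	6	26	29
RVE3	AT1G01520	33	1	8	10	0	0	0	0
CCR16	AT1G02150	60	1	3	8	0	0	0	1
TRA1A	AT2G17930	436	0	3	7	0	0	0	0
DGR2	AT5G25460	40	1	3	4	0	0	2	5
ENTH/ANTH/VHS superfamily protein	AT5G35200	61	1	2	3	0	0	0	0
FLL2	AT1G01320	199	1	0	3	0	0	0	1
Nucleic acid-binding, OB-fold-like protein	AT2G40660	42	1	3	2	0	0	0	0
UBP12	AT5G06600	131	0	0	1	0	0	0	0
PHOT2	AT5G58140	102	0	1	2	0	0	0	0
MLK4	AT3G13670	79	1	0	2	0	0	6	6
UBP13	AT3G11910	131	0	0	2	0	0	1	4
COR27	AT5G42900	27	0	2	1	0	1	4	7
WLIM1	AT1G10200	21	1	1	1	0	0	1	2
CAB4	AT3G47470	28	1	1	1	0	0	1	1
MLK2	AT3G03940	78	0	0	0	1	1	6	7
GRXS17	AT4G04950	53	0	0	0	0	0	1	2
CPNB2	AT3G13470	63	1	0	0	0	0	35	41
LNK3	AT3G12320	31	1	0	0	0	0	18	23
LNK4	AT5G06980	32	0	0	0	0	0	2	6
COP1	AT2G32950	76	1	0	0	0	0	3	4
MLK1	AT5G18190	77	0	0	0	0	0	3	4
SPA1	AT2G46340	115	1	0	0	0	0	1	4
MLK3	AT2G25760	76	0	0	0	0	0	3	0
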