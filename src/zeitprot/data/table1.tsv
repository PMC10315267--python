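protein_name	agi_locus	mw_kda	cycling	LNK1-HFC_ZT5_1	LNK1-HFC_ZT5_2	LNK2-HFC_ZT5_1	LNK2-HFC_ZT5_2	RVE8-HFC_ZT5_1	RVE8-HFC_ZT5_2
LNK1	AT5G64170	70	1	173	56	0	0	107	87
LNK2	AT3G54500	81	1	0	0	468	497	154	149
RVE8	AT3G09600	40	1	22	13	206	223	272	267
RVE6	AT5G52660	36	0	28	14	79	87	0	0
TCF1	AT3G55580	51	1	16	8	37	39	7	4
RVE5	AT4G01280	34	1	16	8	27	33	0	0
RCC1L	AT3G53830	49	1	4	2	8	8	0	0
RVE4	AT5G02840	31	1	4	0	85	84	0	0
CCR16	AT1G02150	60	1	1	0	0	0	0	0
RVE3	AT1G01520	33	1	0	0	10	11	0	0
GRXS17	AT4G04950	53	0	0	0	10	9	0	0
UBP12	AT5G06600	131	0	0	0	8	9	0	0
UBP13	AT3G11910	131	0	0	0	6	7	1	0
RACK1A	AT1G18080	36	1	0	0	2	4	0	0
DGR2	AT5G25460	40	1	0	0	4	3	1	0
PICALM3	AT5G35200	61	1	0	0	4	2	0	0
TRA1A	AT2G17930	436	0	0	0	0	2	0	0
CAB4	AT3G47470	28	1	0	0	1	1	0	0
BTI1	AT4G23630	31	1	0	0	1	1	0	0
PUB12	AT2G28830	107	1	0	0	0	1	0	0
ABA1	AT5G67030	74	1	0	0	0	1	0	0
FLL2	AT1G01320	199	1	0	0	1	0	0	0
WLIM1	AT1G10200	21	1	0	0	1	0	0	0
FINS1	AT1G43670	37	1	0	0	1	0	0	0
PP2A-3	AT2G42500	36	0	0	0	1	0	0	0
Nucleic acid-binding, OB-fold-like protein	AT3G10090	7	0	0	0	1	0	0	0
CPNB2	AT3G13470	63	1	0	0	0	0	31	26
LNK3	AT3G12320	30	1	0	0	0	0	24	25
SAG24	AT1G66580	25	1	0	0	0	0	4	0
LNK4	AT5G06980	32	0	0	0	0	0	3	3
ATRH3	AT5G26742	81	0	0	0	0	0	1	0
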