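protein_name	agi_locus	mw_kda	cycling	YFP-COR27_ZT9_1	YFP-COR27_ZT9_2	YFP-COR27_ZT9_3	YFP-COR27_ZT9_4	GFP-COR28_ZT9_1	GFP-COR28_ZT9_2	GFP-COR28_ZT9_3	GFP-COR28_ZT9_4
COR27	AT5G42900	27	0	89	85	95	80	0	0	0	0
COR28	AT4G33980	26	1	0	0	0	0	22	18	8	10
COP1	AT2G32950	76	1	16	12	19	16	6	6	1	2
SPA1	AT2G46340	115	1	16	12	16	13	4	6	1	0
MLK4	AT3G13670	79	1	16	11	15	12	0	0	0	0
MLK2	AT3G03940	78	0	13	12	15	12	0	0	0	0
PHYD	AT4G16250	129	0	8	7	13	11	0	0	0	0
MLK1	AT5G18190	77	0	10	10	12	10	0	0	0	0
SPA4	AT1G53090	89	0	8	4	11	7	0	0	0	0
SPA2	AT4G11110	115	0	8	6	10	6	0	1	0	0
SF1	AT5G51300	87	0	7	12	7	5	0	0	0	0
RVE8	AT3G09600	40	1	7	5	7	6	3	4	0	3
LNK2	AT3G54500	81	1	6	5	6	3	0	1	0	0
MLK3	AT2G25760	76	0	5	6	6	8	0	0	0	0
LNK1	AT5G64170	70	1	4	4	5	4	4	3	1	0
SPA3	AT3G15354	93	1	4	4	4	4	0	0	0	0
RVE6	AT5G52660	36	0	3	3	4	1	1	0	0	0
RVE5	AT4G01280	34	1	1	1	2	0	1	0	0	0
CCR2	AT2G21660	17	1	1	0	1	1	0	0	0	0
TCF1	AT3G55580	51	1	0	0	1	0	0	0	0	0
PHYE	AT4G18130	123	1	1	0	0	0	0	0	0	0
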