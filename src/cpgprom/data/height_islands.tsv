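gene	island_index	gc_percent	obs_exp	length	five_prime	three_prime	distance	overlaps_tss_flag	far_flag	provenance
ACAN	1	65.7	0.72	1485	87146790	87148274	888	1	0	printed
ADAMTSL3	1	68.7	0.82	1974	82113076	82115050	766	1	0	printed
ADAMTS17	1	60.7	0.65	888	9908373	9907485	8667	0	1	printed
ADAMTS17	2	69.1	0.89	2026	98700323	98698297	617	1	0	printed
ANAPC13	1	59.2	0.788	1548	135688471	135686923	952	1	0	printed
ANKS1	1	55	0.80	660	349633552	349634012	1664	0	0	printed
ANKS1	2	61.7	0.78	1497	34964519	34966016	497	1	0	printed
ATAD5	1	62.6	0.78	1368	26175115	26176483	8031	0	1	printed
ATAD5	2	56.3	0.812	980	26182826	26183806	320	1	0	printed
ATXN3	1	60.4	0.744	1226	91643223	91641997	516	1	0	printed
BCAS3	1	55	0.70	820	56104151	56104971	5803	0	1	printed
BCAS3	2	59.5	0.65	1058	56109366	56110424	588	1	0	printed
BMP2	1	66.7	0.95	1988	6695759	6696745	986	1	0	printed
BMP6	1	66.8	0.87	2687	7670904	7673591	1106	1	0	printed
CABLES1	1	67.4	0.95	2620	18968684	18971304	1041	1	0	printed
CDK6	1	61.2	0.748	2768	92304527	92301759	3379	0	0	printed
CDK6	2	62.1	0.819	1951	92301759	92299808	611	1	0	printed
CENTA2	1	55.1	0.69	532	26263024	26263556	9856	0	1	printed
CENTA2	2	65.9	0.74	1687	26272611	26274298	269	1	0	printed
CHCHD7	1	63.7	0.893	1970	57285833	57287803	1036	1	0	printed
COIL	1	56.3	0.772	1404	52393685	52392281	275	1	0	printed
CPSF2	1	58	0.8	2129	91656710	91658839	1372	1	0	printed
CRLF3	1	55.9	0.817	1084	26183907	26182823	8003	0	1	printed
CRLF3	2	62.6	0.775	1368	26176480	26175112	576	1	0	printed
DCC	1	53.9	0.66	1324	4812170	4813494	399	1	0	printed
DGKE	1	66.7	0.88	2554	52265265	52267819	1287	1	0	printed
DLEU7	1	66.4	0.657	1217	50316345	50315128	459	1	0	printed
DNM3	1	66.1	0.73	1498	170076559	170078057	702	1	0	printed
DNMT3A	1	79.2	0.804	2612	25340227	25342838	248	1	0	printed
DOT1L	1	55	0.68	505	2108150	21081655	6998	0	1	printed
DOT1L	2	55	0.75	498	2110214	2110712	4934	0	1	printed
DOT1L	3	56.1	0.65	586	2113068	2113654	2080	0	0	printed
DOT1L	4	65.3	0.86	2891	2114184	2117075	964	1	0	printed
DYM	1	60.2	0.808	1397	45241580	45240183	503	1	0	printed
EFEMP1	1	58.7	0.683	1350	56004981	56003631	545	1	0	printed
E4F1	1	64.3	0.92	2647	2204610	2207527	8958	0	1	printed
E4F1	2	65.1	0.79	1517	2212727	2214244	841	1	0	printed
FBLN5	1	57.2	0.77	1357	91484395	91483038	607	1	0	printed
FUBP3	1	65.2	0.77	1356	132444169	132445525	612	1	0	printed
GATAD1	1	60.8	0.80	1442	91914227	91915669	474	1	0	printed
GLT25D2	1	65.1	0.771	1841	182273758	182271917	272	1	0	printed
GNA12	1	67.2	0.888	1553	2851125	2849572	640	1	0	printed
GPR126	1	61.6	0.73	1488	142663983	142665471	776	1	0	printed
GRB10	1	67.5	0.965	1964	50829436	50827472	784	1	0	printed
HHIP	1	62.2	0.70	1869	145785471	145787340	1152	1	0	printed
HIST1H1D	1	55	0.667	500	26349982	26349482	6787	0	1	printed
HMGA1	1	67.6	0.79	4212	34310234	34314446	2394	1	0	printed
HMGA2	1	64.4	0.78	3133	64503504	64506637	1003	1	0	printed
IHH	1	70.2	0.765	1908	219634655	219632747	1222	1	0	printed
LBH	1	65.8	0.80	1965	30306777	30308742	1124	1	0	printed
LCORL	1	63.8	0.887	2339	17633555	17631216	1078	1	0	printed
LIN28B	1	55.1	0.89	490	105507480	105507970	3986	0	0	printed
LTBP1	1	65.2	0.909	1292	11650045	11651337	10000	0	1	printed
LYAR	1	61.9	0.69	1379	4343686	4342307	942	1	0	printed
LYN	1	64.9	0.81	1813	56954403	56954926	523	1	0	printed
MOS	1	55	0.945	980	57193889	57192909	3994	0	0	printed
MOS	2	59.9	0.747	1196	57189249	57188053	154	1	0	printed
NCAPG	1	59.3	0.89	1574	17420886	17422460	737	1	0	printed
NOG	1	64.8	0.79	2982	52024564	52027546	1710	1	0	printed
NKX2-1/TTF1	1	60.3	0.67	1661	36064854	36063193	5687	0	1	printed
NKX2-1/TTF1	2	58.5	0.65	1190	36062574	36061384	3407	0	0	printed
NKX2-1/TTF1	3	59.4	0.729	2163	36061089	36058926	1922	1	0	printed
PAPPA	1	64.5	0.85	1373	117955869	117957242	23	1	0	printed
PENK	1	57.8	0.65	536	57523392	57522856	2249	1	0	printed
PENK	2	62.2	0.801	2361	57522705	57520344	1562	1	0	printed
PEX1	1	59.1	0.928	1356	91996364	91995008	583	1	0	printed
PLAGL1	1	63.7	0.893	1970	57287800	57285830	1408	1	0	printed
PNPT1	1	56.1	0.788	909	55774741	55773832	278	1	0	printed
PRKG2	1	57	0.65	574	82354957	82353513	9718	0	1	printed
PTCH1	1	63.6	0.851	2411	97319965	97317554	897	1	0	printed
PXMP3	1	58.6	0.79	1303	78075931	78074628	852	1	0	printed
RAB40C	1	69.7	0.91	2715	578292	581007	1885	1	0	printed
RBBP8	1	58.7	0.90	1476	18766793	18768269	500	1	0	printed
RNF135	1	59.2	0.77	1234	26321702	26322936	380	1	0	printed
RPS20	1	55.1	0.951	1047	57150084	57149037	461	1	0	printed
SCMH1	1	68.7	0.798	1999	41481234	41479235	859	1	0	printed
SCUBE3	1	63.1	0.77	2003	35288777	35290780	1391	1	0	printed
SF3B4	1	56.1	0.651	879	148166783	148165904	457	1	0	printed
SH3GL3	1	62.6	0.73	1773	81906488	81908261	799	1	0	printed
SOCS2	1	66.4	0.82	2790	92487649	92490439	80	1	0	printed
SPAG1	1	58.1	0.77	1239	101238989	101240228	450	1	0	printed
TBX2	1	67.3	0.81	5974	56827581	56833555	4458	1	0	printed
TBX4	1	67.1	0.74	1700	56883545	56885245	5044	0	1	printed
TBX4	2	62.3	0.81	1298	56886293	56887591	2296	0	0	printed
TBX4	3	64.6	0.72	1516	56888304	56889820	285	1	0	printed
TCP11	1	67.1	0.718	1134	35217617	35216483	452	1	0	printed
TGS1	1	59.5	0.8	1400	56847635	56849035	710	1	0	printed
TMED3	1	66.8	0.71	1133	77389985	77391118	561	1	0	printed
TRIM25	1	63.6	0.751	1460	52347061	52345601	653	1	0	printed
TRIP11	1	56.4	0.768	1310	91576732	91575422	593	1	0	printed
UQCC/GDF5	1	56.3	0.651	774	33463669	33462895	422	1	0	printed
WDR60	1	60.7	0.82	1440	158341361	158342801	669	1	0	printed
ZFHX4	1	55	0.78	540	77748585	77749125	7485	0	1	printed
ZFHX4	2	56.6	0.72	1064	77752435	77743499	3635	0	0	printed
ZFHX4	3	55	0.85	545	77755726	77746271	344	1	0	printed
ZNF76	1	64.5	0.78	1490	35334502	35335992	986	1	0	printed
ZNF462	1	55.4	0.72	1475	108661904	108663379	3295	0	0	printed
ZNF462	2	61.9	0.65	507	108664296	108664803	903	0	0	printed
ZNF678	1	66.4	0.66	1300	225814864	108666164	3003	0	0	printed
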