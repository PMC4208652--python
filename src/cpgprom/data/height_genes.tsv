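gene	refseq	chrom	tss	studies	housekeeping	methylation_regulated	methylation_regulator	no_methylation_evidence
ACAN	NM_013227	15	87147678	W2008;C2009	0	0	0	1
ADAMTSL3	NM_207517	15	82113842	G2008;L2008;W2008	0	1	0	0
ADAMTS17	NM_139057	15	98699706	G2008	0	1	0	0
AGPAT6	NM_178819	8	41554876	L2008	0	0	0	0
ANAPC13	NM_155391	3	135687519	W2008	0	0	0	0
ANKS1	NM_015245	6	34965016	G2008	0	0	0	1
ATAD5	NM_024857	17	26183149	G2008	0	0	0	0
ATXN3	NM_030660	14	91642718	G2008	0	0	0	0
BCAS3	NM_001099432	17	56109954	G2008;C2009	0	0	0	0
BMP2	NM_001200	20	6696745	G2008	0	1	0	0
BMP6	NM_001718	6	7672010	G2008	0	1	0	0
CABLES1	NM_001107404	18	18969725	G2008	1	1	0	0
CDK6	NM_001259	7	92301148	G2008;L2008;W2008	0	0	0	0
CENTA2	NM_018404	17	26272880	G2008	0	0	0	0
CHCHD7	NM_024300	8	57286869	G2008;L2008	0	0	0	0
COIL	NM_004645	17	52393410	G2008	0	0	0	0
CPSF2	NM_175808	13	91658090	G2008	1	0	0	0
CRLF3	NM_015986	17	26175904	G2008	0	0	0	0
DCC	NM_005215	18	48120569	L2008	0	1	0	0
DEF6	NM_022047	6	35373573	G2008	0	0	0	0
DGKE	NM_003647	17	52266552	G2008	0	0	0	0
DLEU7	NM_198989	13	50315886	W2008	0	1	0	0
DNM3	NM_015569	1	170077261	G2008	0	0	0	0
DNMT3A	NM_175629	2	25342590	G2008	0	0	1	0
DOT1L	NM_032482	19	2115148	L2008	0	0	1	0
DYM	NM_017653	18	45241077	W2008	0	0	0	0
EFEMP1	NM_004105	2	56003860	G2008;W2008;C2009	0	1	0	0
E4F1	NM_004424	16	2213568	L2008	0	0	0	0
FBLN5	NM_006329	14	91483799	G2008;L2008	0	0	0	0
FBP2	NM_003837.2	9	97321226	C2009	0	0	0	1
FUBP3	NM_003934	9	132444781	L2008	0	0	0	0
GATAD1	NM_021167	7	91914701	G2008	0	0	0	0
GLT25D2	NM_015101	1	182273486	G2008	0	0	0	0
GNA12	NM_007353	7	2850485	G2008	1	0	0	0
GPR126	NM_001032395	6	142664749	G2008;L2008	0	0	0	0
GRB10	NM_001001549	7	50767544	L2008	0	1	0	0
HHIP	NM_022475	4	145786623	G2008;L2008;W2008;C2009	0	1	0	0
HIST1H1D	NM_005320	6	26343195	L2008	0	0	1	0
HMGA1	NM_145899	6	34312628	G2008;C2009	0	0	1	0
HMGA2	NM_003483	12	64504507	G2008;L2008;W2008;C2009	0	0	1	0
IHH	NM_002191	2	219633433	W2008	0	0	0	0
LBH	NM_030915	6	30307901	G2008	0	0	0	0
LCORL	NM_153686	4	17632483	G2008;W2008;C2009	0	0	0	0
LIN28B	NM_001004317	6	105511616	L2008	0	0	0	0
LTBP1	NM_206943.2	2	452207	C2009	0	0	0	0
LYAR	NM_017816	4	4342744	L2008	0	0	0	0
LYN	NM_001111097	8	56954940	G2008	0	0	0	0
MOS	NM_022746	8	57189095	G2008	0	1	0	0
MTMR11	NM_181873	1	148174867	G2008	0	0	0	0
NACA2	NM_199290	17	57023345	G2008	0	0	0	1
NCAPG	NM_022346	4	17421623	G2008;C2009	0	0	0	0
NOG	NM_005450	17	52026059	G2008	0	0	0	0
NKX2-1/TTF1	NM_003317	14	36055353	L2008	0	1	0	0
PAPPA	NM_002581	9	117955892	L2008	0	0	0	0
PENK	NM_006211	8	57521143	G2008	0	1	0	0
PEX1	NM_000466	7	91995781	G2008	0	0	0	0
PLAGL1	NM_002655	8	57286413	G2008;C2009	0	1	0	0
PNPT1	NM_033109	2	55774515	G2008	0	0	0	0
PRKG2	NM_006259	4	82345239	L2008	0	0	0	0
PTCH1	NM_001083605	9	97319068	W2008;C2009	0	1	0	0
PXMP3	NM_001079867	8	78075079	G2008	1	0	0	0
RAB40C	NM_021168	16	580180	L2008	0	0	0	0
RBBP8	NM_203291	18	18767837	G2008	0	1	0	0
RDHE2	NM_138969	8	57395795	G2008;L2008	0	0	0	0
RNF135	NM_197939	17	26322082	G2008	0	0	0	0
RPS20	NM_001023	8	57149623	G2008	0	0	0	0
SCMH1	NM_012236	1	41480375	W2008	1	0	0	0
SCUBE3	NM_152753	6	35290168	G2008	0	0	0	0
SF3B4	NM_005850	1	148166326	G2008	0	0	0	0
SH3GL3	NM_003027	15	81907287	L2008	0	0	0	0
SOCS2	NM_003877	12	92487729	G2008;W2008;C2009	0	1	0	0
SPAG1	NM_003114	8	101239832	W2008;C2009	0	0	0	0
SV2A	NM_014849	1	148156054	G2008	0	0	0	0
TBX2	NM_005994	17	56832039	G2008	0	0	0	0
TBX4	NM_001003006	17	56888634	G2008	0	0	0	0
TCP11	NM_018679	6	35217165	G2008	0	0	0	0
TGS1	NM_024831	8	56848345	G2008	0	0	0	0
TMED3	NM_007364	15	77390546	L2008	0	0	0	0
TRIM25	NM_005082	17	52346408	G2008	0	0	0	0
TRIP11	NM_004239	14	91576570	G2008;L2008	0	0	0	0
UQCC/GDF5	NM_018244	20	33463247	G2008;L2008;W2008;C2009	0	0	0	0
WDR60	NM_01851	7	158342030	L2008	0	0	0	0
ZBTB38	NM_001080412	3	142525745	G2008;L2008;W2008;C2009	0	0	1	1
ZFHX4	NM_024721	8	77756070	G2008	0	0	0	0
ZNF76	NM_003427	6	35335488	G2008	0	0	0	0
ZNF462	NM_021224	9	108665199	G2008	0	0	0	0
ZNF678	NM_178549	1	225817867	W2008;C2009	0	0	0	0
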