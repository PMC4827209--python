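family	T. lutea	Pavlova sp.	E. huxleyi	P. tricornutum	N. gaditana	P. purpureum	C. reinhardtii
ABI3/VP1	1	0	0	0	0	0	1
AP2	1	1	58	0	2	0	6
ERF	1	6	99	2	2	0	9
bHLH	0	0	0	8	3	3	8
bZIP	3	3	6	25	11	21	20
C2C2-CO-like	0	0	0	0	0	0	1
C2C2-Dof	0	0	0	0	0	0	1
C2C2-GATA	5	1	4	0	0	2	12
C2C2-LSD	1	1	0	0	0	0	1
C2H2	8	8	37	4	5	60	5
C3H	13	7	47	11	5	8	22
CCAAT	3	0	2	3	3	3	1
CPP	1	0	4	5	1	2	3
CSD	3	4	25	5	1	3	2
DBB	0	0	0	0	0	1	0
E2F/DP	2	3	3	5	1	3	3
Fungal TRF	14	8	27	1	10	0	0
GARP-G2-like	4	4	5	2	0	2	4
GARP-ARR-B	0	0	0	0	0	0	1
HB-other	16	14	28	0	0	2	1
TALE	1	1	0	4	0	9	3
HSF	9	8	8	67	4	1	2
LIM	2	3	11	0	0	2	1
M-type	3	1	1	0	0	2	2
mTERF	5	0	6	5	2	5	4
MYB (3R)	1	0	3	2	5	1	1
MYB (2R)	25	20	39	11	8	23	10
MYB-rel	21	15	51	7	7	7	18
MYB-SHAQKYF	1	2	1	7	8	16	4
NF-X1	0	0	0	0	0	0	1
NF-YA	0	1	1	1	1	1	0
NF-YB	1	1	4	2	2	3	3
NF-YC	3	4	1	8	6	6	2
Nin-like	0	1	0	0	1	4	15
S1Fa-like	0	0	0	0	0	0	1
SBP	0	0	0	0	0	0	23
Sigma-70	4	4	2	8	4	8	1
TUB	3	7	5	3	1	0	6
VARL	0	0	0	0	0	0	12
Whirly	0	0	0	0	0	0	1
WRKY	0	0	0	0	0	0	1
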