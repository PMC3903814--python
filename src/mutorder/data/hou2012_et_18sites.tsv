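site	1	2	3	5	6	7	8	9	12	16	18	19	20	22	24	25	26	29	30	31	36	37	40	41	43	44	45	47	48	49	50	52	54	56	60	61	63	66	69	70	72	73	74	76	78	79	80	82	86	87	88	89	90	91	93	94	97	100
PDE4DIP(A>G)	-	-	-	1	1	0	-	0	-	-	-	0	-	-	-	-	-	-	1	-	-	-	0	-	0	-	1	0	-	-	-	-	-	1	-	0	-	-	-	0	-	0	1	0	0	-	0	0	1	-	0	-	-	-	-	1	1	-
NTRK1(A>G)	-	0	-	-	1	-	-	-	-	2	-	2	1	1	-	-	1	-	2	-	-	1	-	-	0	0	-	-	2	-	2	1	0	-	-	1	-	-	0	1	1	-	0	0	1	1	0	1	-	0	-	-	0	-	0	0	1	2
SESN2(C>T)	1	1	1	-	-	-	-	1	1	1	2	-	-	1	-	-	-	0	0	1	-	2	2	-	0	2	0	1	1	1	0	0	0	1	-	1	0	1	-	-	1	0	1	2	2	-	1	1	1	2	1	0	0	1	2	2	1	1
ARHGAP5(G>A)	-	1	-	-	-	0	0	2	-	-	-	-	0	1	1	-	-	-	-	0	-	1	-	-	0	-	0	0	-	1	0	-	-	0	0	-	-	0	-	1	0	0	0	-	0	0	1	1	-	0	0	-	-	0	1	0	1	0
DNAJC17(C>G)	1	-	1	-	-	-	-	0	-	1	0	-	-	-	-	-	-	2	1	-	-	-	-	-	1	2	-	2	1	1	-	1	0	1	1	-	1	1	1	1	2	-	1	0	1	0	1	1	-	1	-	0	-	-	1	-	2	1
USP32(C>T)	-	-	-	1	0	-	-	1	-	-	-	-	0	0	0	-	-	-	0	-	-	-	-	-	-	1	0	1	0	0	0	1	0	1	0	0	-	1	0	0	-	-	-	-	-	0	-	0	1	-	0	1	1	-	0	0	0	-
ANAPC1(G>A)	-	-	-	1	0	1	0	1	-	1	0	-	1	1	0	1	1	0	2	-	0	-	-	0	0	0	0	1	-	0	0	1	-	0	-	-	0	0	1	-	0	-	0	0	-	-	-	1	0	-	0	0	-	-	-	0	-	0
RETSAT(C>T)	-	0	-	1	0	0	-	-	-	0	-	-	-	0	-	0	0	-	0	-	0	-	0	-	0	-	0	0	-	1	0	1	0	-	0	1	0	0	1	0	0	-	0	1	1	-	1	0	0	-	0	0	-	1	1	0	0	-
ST13(G>A)	0	0	-	-	-	-	0	1	1	1	-	0	1	-	-	1	-	-	1	0	1	1	-	0	0	1	-	1	-	-	0	1	-	1	1	1	1	1	1	0	1	-	0	-	0	1	1	0	1	1	1	0	1	1	0	-	1	0
DLEC1(T>C)	-	-	-	-	-	-	-	1	-	1	-	-	0	2	2	2	-	-	1	-	-	1	-	-	-	-	2	1	1	-	-	-	2	-	2	-	-	1	-	-	-	-	2	2	0	1	-	-	-	-	-	-	-	0	2	-	-	1
FRG1(G>A)	0	0	1	0	0	-	0	-	0	0	0	0	-	-	-	0	-	-	0	-	-	-	0	0	0	-	0	1	0	0	0	0	-	0	0	1	1	0	-	0	0	0	0	0	0	0	0	1	1	0	-	1	0	-	0	0	0	0
DMXL1(G>A)	2	-	-	1	-	0	-	1	-	2	-	-	-	2	-	0	0	1	1	-	2	-	1	-	0	-	-	-	-	1	-	1	-	1	1	0	0	1	-	1	-	-	-	-	2	-	-	-	0	-	-	0	-	1	-	0	2	-
FAM115C(T>C)	-	-	-	-	0	-	-	-	-	-	-	0	-	-	-	-	0	-	-	-	-	-	-	-	-	2	0	0	-	-	-	-	-	1	-	-	-	-	-	-	-	-	0	-	1	-	-	-	-	0	-	1	-	-	-	-	-	-
MLL3(C>T)	-	-	0	-	0	0	-	0	0	0	1	-	0	-	0	-	0	0	1	0	1	1	0	-	0	0	0	-	-	0	1	1	1	-	1	0	-	0	-	0	-	0	0	-	-	0	0	0	0	0	-	0	0	-	1	-	-	0
ABCB5(G>T)	1	-	-	1	-	-	1	2	1	0	1	-	-	0	0	-	-	2	2	-	-	2	-	-	-	-	1	-	-	-	-	-	-	1	1	1	-	1	0	0	-	-	1	0	-	1	0	-	1	-	-	1	-	-	-	-	0	-
ASNS(T>A)	0	0	0	0	0	0	0	1	-	0	0	0	-	0	0	1	1	0	-	0	1	1	1	-	0	1	0	-	0	-	1	-	0	-	1	-	-	0	-	0	0	-	0	0	1	0	1	0	0	0	0	0	0	0	-	-	1	0
PABPC1(C>T)	0	0	0	0	0	0	0	-	1	-	0	-	-	0	0	0	-	-	0	0	-	0	0	-	1	0	-	0	0	0	0	0	0	-	0	-	0	0	0	0	-	-	0	-	0	-	0	1	0	0	-	0	-	0	1	-	0	0
TOP1MT(A>G)	-	-	-	-	-	-	-	-	-	-	-	0	-	-	-	-	-	-	-	0	2	2	1	-	-	1	-	1	-	1	2	-	2	2	0	-	-	-	-	1	-	1	-	1	-	-	1	2	-	-	-	-	2	1	-	0	-	1
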