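number	tmd_id	protein	subset	blind_test	sequence
1	O75460	Ire1	ETRA	1	ATIILSTFLLIGWVAFIITY
2	P05026	ATP1B1	ETRA	1	LLFYVIFYGCLAGIFIGTIQVMLLTI
3	P23470	PTPRG	ETRA	0	IIPLIVVSALTFVCLILLIAVLV
4	P35590	Tie1	ETRA	0	LILAVVGSVSATCLTILAALLTLV
5	Q08345	DDR1	ETRA	0	ILIGCLVAIILLLLLIIALML
6	Q16827	PTPRO	ETRA	0	VVVISVLAILSTLLIGLLLVTLIIL
7	Q7L4S7	Armcx6	ETRA	0	REVGWMAAGLMIGAGACYCV
8	Q92729	PTPRU	ETRA	0	LILGICAGGLAVLILLLGAIIVII
9	Q9Y286	Siglec7	ETRA	0	VLLGAVGGAGATALVFLSFC
10	P02724	GpA	ETRA	0	LIIFGVMAGVIGTIL
11	P04626	ErbB2	ETRA	0	LTSIISAVVGILLVVVLGVVFGIL
12	P05106	ITGB3	ETRA	0	VLLSVMGAILLIGLAALLI
13	P08514	ITGA2B	ETRA	1	WVLVGVLGGLLLLTILVLAMW
14	P0A6S5	FtsB	ETRA	0	TLLLLAILVWLQYSLWF
15	P13224	GP1BB	ETRA	0	GALAAQLALLGLGLLHALLL
16	P25189	MPZ	ETRA	0	YGVVLGAVIGGVLGVVLLLLLLFYVV
17	Q12913	PTPRJ	ETRA	0	ICGAVFGCIFGALVIVTVGG
18	Q12983	BNIP3	ETRA	1	LLSHLLAIGLGIYIG
19	Q6ZRP7	QSOX2	ETRA	0	CVVLYVASSLFLMVMY
20	Q8NI60	ADCK3	ETRA	0	LANFGGLAVGLGFGALA
21	Q99IB8	NS4A	ETRA	0	TWVLAGGVLAAVAAYCLAT
22	P20963	CD3zeta	NMR	1	LCYLLDGILFIYGVILTALFL
23	P21709	EphA1	NMR	0	IVAVIFGLLLGAALLLGILVF
24	O43914	TYROBP	NMR	0	LAGIVMGDLVLTVLIALAVYFL
25	P05067	APP	NMR	0	AIIGLMVGGVVIATVIVITLVML
26	P09619	PDGFRB	NMR	0	VVVISAILALVVLTIISLIILIMLW
27	P22607	FGFR3	NMR	0	VYAGILSYGVGFFLFLLVVAAVTLC
28	O15455	TLR3	NMR	1	FFMINTSILLIFIFIVLL
29	O14763	DR5	NMR	0	SGIIIGVTVAAVVLIVAVFVCKSLL
30	1orqC4	KvAP	XRAY	0	GKVIGIAVMLTGISALTLLIGTVSNMFQ
31	1xioA4	Bacteriorhodopsin	XRAY	0	GFLMSTQIVVITSGLIADL
32	2axtM1	PSII-M	XRAY	0	ATALFVLVPSVFLIILYV
33	2h8aA2	Mgst1	XRAY	0	HLNDLENIVPFLGIGLLYSL
34	2j58A1	Wza	XRAY	1	SQLVPTISGVHDMTETVRYI
35	3h9vA2	P2X-purinoceptor	XRAY	0	KFNIIPTLLNIGAGLALLGLVNVICDWIV
36	3rifA2	GluCl-alpha	XRAY	0	IPARVTLGVTTLLTMTAQSAGIN
37	3spcA2	KCNJ12	XRAY	0	PLAVFMVVVQSIVGCIIDSFMIGAIMAKM
38	3zk1A1	ATPase-F0-c-ring	XRAY	1	LGCSAVGAGLAMIAGLGPGIGEG
39	4hksA1	CRCM1	XRAY	0	SWTSALLSGFAMVAMVE
40	4i0uA1	CorA	XRAY	0	TIIATIFMPLTFIAGIYGMNF
41	4o9pC1	pntAB	XRAY	0	WSALYIFVLTAFLGYEL
42	4r0cA7	AbgT	XRAY	0	ITAMEVTMASMAGYLVLMFFAAQFVAWF
43	4ryiA2	TspO	XRAY	1	PGMTIGMIWAVLFGLIALSVA
44	4wisA1	TMEM16	XRAY	0	LKAWGLLLSILFAEHFYLVVQLAVR
45	5irzD6	Trpv1	XRAY	0	KAVFIILLLAYVILTYILLLNMLIALM
46	5nkqA1	CRCB-TM1	XRAY	1	FIAIGIGATLGAWLRWVLG
47	5nkqA3	CRCB-TM3	XRAY	0	AAVTGFLGGLTTFSTFSAETV
48	5t4dA6	PC2	XRAY	0	RVLGPIYFTTFVFFMFFILLNMFLAIIN
49	5u6oA6	BCNG-1	XRAY	0	ITMLSMIVGATCYAMFVGHATALI
50	5uldA9	NadC	XRAY	0	WKEIQKTADWGILLLFGGGLCL
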