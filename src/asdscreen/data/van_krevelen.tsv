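# Hoftyzer-van Krevelen group contributions: dispersive and polar
# attraction constants Fd, Fp ((J cm3)^0.5/mol), hydrogen-bond
# cohesive energy Eh (J/mol); molar volumes V (cm3/mol) shared
# with the Fedors column (standard pairing).
method	van_krevelen
label	Fd	Fp	Eh	V
CH3	420	0	0	33.5
CH2	270	0	0	16.1
CH	80	0	0	-1.0
C	-70	0	0	-19.2
CH2=	400	0	0	28.5
=CH-	200	0	0	13.5
=C<	70	0	0	-5.5
phenyl	1430	110	0	71.4
phenylene	1270	110	0	52.4
phenyl_trisub	1270	110	0	33.4
ring	190	0	0	16.0
OH	210	500	20000	10.0
O	100	400	3000	3.8
C=O	290	770	2000	10.8
COO	390	490	7000	18.0
COOH	530	420	10000	28.5
NH2	280	0	8400	19.2
NH	160	210	3100	4.5
N	20	800	5000	-9.0
N=	20	800	5000	-2.7
Cl	450	550	400	24.0
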