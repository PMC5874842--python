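# Fedors group contributions: cohesive energy E (J/mol) and
# molar volume V (cm3/mol). Negative V entries are branching/
# ring-junction corrections.
method	fedors
label	E	V
CH3	4710	33.5
CH2	4940	16.1
CH	3430	-1.0
C	1470	-19.2
CH2=	4310	28.5
=CH-	4310	13.5
=C<	4310	-5.5
phenyl	31940	71.4
phenylene	31940	52.4
phenyl_trisub	31940	33.4
ring	1050	16.0
conjugation	1670	-2.2
OH	29800	10.0
O	3350	3.8
C=O	17370	10.8
CHO	21350	22.3
COO	18000	18.0
COOH	27630	28.5
NH2	12560	19.2
NH	8370	4.5
N	4190	-9.0
N=	11720	-2.7
CONH2	41860	17.5
CONH	33490	9.5
CON<	29260	-7.7
Cl	11550	24.0
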