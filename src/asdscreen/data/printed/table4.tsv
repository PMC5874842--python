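# Published screening-criterion values per drug-polymer pair:
# Greenhalgh differences (Fedors/van Krevelen), Flory-Huggins chi
# (Fedors/van Krevelen), Bagley-plot Euclidean distance.
drug	polymer	delta_diff_f	delta_diff_vk	chi_f	chi_vk	euc_d
IBU	HP50	5.9	7.4	3.1	4.6	9.8
IBU	HAS	5.0	6.9	2.3	4.1	10.2
IBU	PK30	6.5	6.9	3.6	4.1	6.9
IBU	PVA	4.2	5.0	1.7	2.3	4.9
IBU	SOL	2.2	3.2	0.7	1.2	3.2
IBU	EUD	2.1	3.2	0.7	1.2	4.3
IBU	EUD55	2.4	3.1	0.8	1.1	4.3
NAP	HP50	3.4	4.9	1.2	2.3	8.4
NAP	HAS	2.5	4.4	0.8	1.9	9.2
NAP	PK30	4.0	4.4	1.5	1.9	4.4
NAP	PVA	1.7	2.5	0.6	0.9	2.5
NAP	SOL	0.3	0.7	0.4	0.4	0.8
NAP	EUD	0.4	0.7	0.4	0.4	3.2
NAP	EUD55	0.1	0.6	0.3	0.4	3.2
CAR	HP50	1.3	1.8	0.4	0.6	7.1
CAR	HAS	2.2	1.3	0.6	0.5	8.3
CAR	PK30	0.7	1.4	0.4	0.5	1.6
CAR	PVA	2.9	0.5	0.9	0.4	0.8
CAR	SOL	5.0	2.3	1.9	0.7	2.4
CAR	EUD	5.1	2.3	1.9	0.7	3.8
CAR	EUD55	4.8	2.4	1.8	0.7	3.8
ITR	HP50	0.3	0.7	0.4	0.4	6.0
ITR	HAS	0.6	0.3	0.4	0.4	7.3
ITR	PK30	0.9	0.3	0.5	0.4	1.9
ITR	PVA	1.4	1.6	0.7	0.8	1.8
ITR	SOL	3.4	3.4	2.3	2.4	3.6
ITR	EUD	3.5	3.4	2.4	2.4	4.0
ITR	EUD55	3.2	3.5	2.1	2.5	4.1
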