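# Published solubility parameters (MPa^0.5) and molar volumes (cm3/mol)
# per compound: Fedors total, van Krevelen total and components.
abbr	role	delta_f	delta_vk	delta_d	delta_p	delta_h	v_f	v_vk
IBU	drug	20.9	19.4	17.9	2.2	7.2	195.5	195.5
NAP	drug	23.4	21.9	20.1	3.0	8.0	178.3	203.1
CAR	drug	28.1	24.9	22.0	6.6	9.6	154.1	168.8
ITR	drug	26.6	26.0	22.8	6.0	10.9	403.6	434.5
HP50	polymer	26.8	26.7	20.8	3.8	16.4	384.5	384.5
HAS	polymer	25.9	26.3	19.4	4.3	17.2	344.5	344.5
PK30	polymer	27.4	26.3	20.4	13.7	9.3	71.7	81.2
PVA	polymer	25.1	24.4	19.2	11.2	9.7	69.7	75.4
SOL	polymer	23.1	22.6	18.6	9.2	8.7	83.9	89.3
EUD	polymer	23.0	22.6	18.5	6.6	11.1	70.4	70.4
EUD55	polymer	23.3	22.5	18.4	6.6	11.1	70.8	70.8
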