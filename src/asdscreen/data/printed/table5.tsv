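# Published top-3 polymer rankings per predictive method and drug, with the
# printed position/identity agreement scores against the spray-dryer
# reference (empty for the reference itself).
method	drug	ranking	f1	f2
delta_chi_F	IBU	EUD>SOL>EUD55	0	0.33
delta_chi_F	NAP	EUD55>SOL>EUD	0.33	0.33
delta_chi_F	CAR	PK30>HP50>HAS	0	0.33
delta_chi_F	ITR	HP50>HAS>PK30	0	0.33
delta_chi_VK	IBU	EUD55>EUD>SOL	0.33	0.33
delta_chi_VK	NAP	EUD55>EUD>SOL	0	0.33
delta_chi_VK	CAR	PVA>HAS>PK30	0	0.33
delta_chi_VK	ITR	HAS>PK30>HP50	0.33	0.33
EUC	IBU	SOL>EUD55>EUD	0	0.33
EUC	NAP	SOL>PVA>EUD	0.66	0.66
EUC	CAR	PVA>PK30>SOL	0.33	0.33
EUC	ITR	PVA>PK30>SOL	0	0
FC_RT	IBU	PK30>PVA>SOL	1	1
FC_RT	NAP	SOL>PK30>HAS	0	0.33
FC_RT	CAR	EUD>PK30>HAS	0.66	0.66
FC_RT	ITR	EUD>EUD55>HP50	1	1
FC_RP	IBU	PVA>PK30>SOL	0.33	1
FC_RP	NAP	SOL>PVA>PK30	0.33	0.66
FC_RP	CAR	PK30>EUD>HAS	0	0.66
FC_RP	ITR	HAS>HP50>EUD55	0	0.66
QC	IBU	PK30>PVA>HAS	0.66	0.66
QC	NAP	PK30>PVA>SOL	0.66	0.66
QC	CAR	PK30>PVA>SOL	0	0.33
QC	ITR	EUD>EUD55>HAS	0.66	0.66
AD	IBU	PK30>PVA>SOL	1	1
AD	NAP	PK30>PVA>SOL	0.66	0.66
AD	CAR	EUD>PK30>EUD55	1	1
AD	ITR	EUD>EUD55>HP50	1	1
SD	IBU	PK30>PVA>SOL		
SD	NAP	PK30>PVA>EUD		
SD	CAR	EUD>PK30>EUD55		
SD	ITR	EUD>EUD55>HP50		
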