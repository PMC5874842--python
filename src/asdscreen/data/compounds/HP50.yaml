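abbreviation: HP50
name: Hypromellose phthalate (HPMCP-HP50)
role: polymer
mw: 78000.0
true_density: 1.82
tg_c: 140.0
group_counts:
  fedors:
    O: 8.2661
    CH: 12.2661
    CH2: 4.2661
    CH3: 4.2661
    OH: 3.0804
    ring: 2.0
    phenylene: 0.9196
    COO: 0.9196
    COOH: 0.9196
  van_krevelen:
    O: 7.5761
    CH: 11.7999
    CH2: 3.7999
    CH3: 3.5761
    OH: 2.9607
    ring: 2.0
    phenylene: 1.2632
    COO: 1.2632
    COOH: 1.2632
notes: Repeat unit = two anhydroglucose rings with fractional methoxyl/hydroxypropyl/phthalyl
  substitution pinned to reproduce the published parameters (substituent proportions
  of commercial grades span a range).
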