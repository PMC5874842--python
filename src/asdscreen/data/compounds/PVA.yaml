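abbreviation: PVA
name: PVPVA (vinylpyrrolidone-vinyl acetate 6:4)
role: polymer
mw: 57500.0
true_density: 1.27
tg_c: 112.0
repeat_units:
- name: vinylpyrrolidone
  fraction: 0.6
  group_counts:
    fedors:
      CH2: 4
      CH: 1
      CON<: 1
      ring: 1
    van_krevelen:
      CH2: 4
      CH: 1
      N: 1
      C=O: 1
      ring: 1
- name: vinyl acetate
  fraction: 0.4
  group_counts:
    fedors: &id001
      CH2: 1
      CH: 1
      COO: 1
      CH3: 1
    van_krevelen: *id001
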