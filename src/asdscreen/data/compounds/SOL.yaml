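abbreviation: SOL
name: Soluplus (caprolactam-vinyl acetate-ethylene glycol graft)
role: polymer
mw: 115000.0
true_density: 1.03
tg_c: 80.0
repeat_units:
- name: vinylcaprolactam
  fraction: 0.57
  group_counts:
    fedors:
      CH2: 6
      CH: 1
      CON<: 1
      ring: 1
    van_krevelen:
      CH2: 6
      CH: 1
      N: 1
      C=O: 1
      ring: 1
- name: vinyl acetate
  fraction: 0.3
  group_counts:
    fedors: &id001
      CH2: 1
      CH: 1
      COO: 1
      CH3: 1
    van_krevelen: *id001
- name: ethylene glycol
  fraction: 0.13
  group_counts:
    fedors: &id002
      CH2: 2
      O: 1
    van_krevelen: *id002
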