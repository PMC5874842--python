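abbreviation: EUD55
name: Eudragit L100-55 (methacrylic acid-ethyl acrylate 1:1)
role: polymer
mw: 320000.0
true_density: 1.25
tg_c: 122.0
repeat_units:
- name: methacrylic acid
  fraction: 0.5
  group_counts:
    fedors: &id001
      CH2: 1
      C: 1
      CH3: 1
      COOH: 1
    van_krevelen: *id001
- name: ethyl acrylate
  fraction: 0.5
  group_counts:
    fedors: &id002
      CH2: 2
      CH: 1
      CH3: 1
      COO: 1
    van_krevelen: *id002
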