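abbreviation: IBU
name: Ibuprofen
role: drug
mw: 206.0
tg_c: -44.0
tm_c: 76.0
gfa_class: III
group_counts:
  fedors: &id001
    CH3: 3
    CH: 2
    CH2: 1
    phenylene: 1
    COOH: 1
  van_krevelen: *id001
notes: '2-(4-isobutylphenyl)propanoic acid; identical fragmentation under both methods:
  3 CH3, 2 CH, 1 CH2, p-phenylene, COOH.'
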