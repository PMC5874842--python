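abbreviation: NAP
name: Naproxen
role: drug
mw: 230.0
tg_c: 6.0
tm_c: 158.0
gfa_class: I
group_counts:
  fedors:
    CH3: 2
    CH: 1
    COOH: 1
    O: 1
    phenylene: 1
    =CH-: 2
    =C<: 2
    ring: 1
    conjugation: 2
  van_krevelen:
    CH3: 2
    CH: 1
    COOH: 1
    O: 1
    phenylene: 2
notes: 'Fedors: naphthalene core as phenylene + 2 =CH- + 2 =C< + ring closure +
  2 conjugation corrections. The van Krevelen table has no condensed-aromatic corrections,
  so the core is two fused phenylene rings there (handled by omission).'
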