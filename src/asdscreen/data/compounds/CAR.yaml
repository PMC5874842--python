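abbreviation: CAR
name: Carbamazepine
role: drug
mw: 236.0
tg_c: 50.0
tm_c: 177.0
gfa_class: I
group_counts:
  fedors:
    phenylene: 2
    =CH-: 2
    N: 1
    CONH2: 1
    ring: 1
    conjugation: 1
  van_krevelen:
    phenylene: 2
    =CH-: 2
    N: 1
    NH2: 1
    C=O: 1
    ring: 1
notes: Dibenzazepine with a carboxamide. Fedors uses the CONH2 composite; the van
  Krevelen table lacks amide entries, so the carboxamide is split into NH2 + C=O
  there.
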