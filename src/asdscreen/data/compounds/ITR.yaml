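abbreviation: ITR
name: Itraconazole
role: drug
mw: 705.0
tg_c: 59.0
tm_c: 168.0
gfa_class: III
group_counts:
  fedors:
    CH3: 2
    CH2: 8
    CH: 2
    C: 1
    phenylene: 2
    phenyl_trisub: 1
    Cl: 2
    O: 3
    C=O: 1
    =CH-: 3
    ring: 4
    N: 6
    N=: 2
    conjugation: 11
  van_krevelen:
    CH3: 2
    CH2: 8
    CH: 2
    C: 1
    phenylene: 2
    phenyl_trisub: 1
    Cl: 2
    O: 3
    C=O: 1
    =CH-: 3
    ring: 4
    N: 5
    N=: 3
notes: Triazole/triazolone/piperazine/dioxolane fragmentation. Fedors adds conjugation
  corrections for the azole and aryl ring systems and treats the amide-adjacent
  ring nitrogen as tertiary amine; omitted under van Krevelen.
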