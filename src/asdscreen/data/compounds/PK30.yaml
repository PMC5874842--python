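abbreviation: PK30
name: Polyvinylpyrrolidone K30
role: polymer
mw: 50000.0
true_density: 1.18
tg_c: 162.0
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
notes: Vinylpyrrolidone repeat unit; the lactam is the Fedors CON< composite, split
  into N + C=O under van Krevelen.
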