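abbreviation: HAS
name: Hypromellose acetate succinate (HPMCAS-LF)
role: polymer
mw: 18167.0
true_density: 1.29
tg_c: 122.0
group_counts:
  fedors:
    O: 7.1359
    CH: 11.1359
    CH2: 4.9883
    CH3: 4.0359
    OH: 2.1738
    ring: 2.0
    COO: 1.8262
    COOH: 0.9262
  van_krevelen:
    O: 8.1987
    CH: 12.4306
    CH2: 4.9755
    CH3: 4.6987
    OH: 3.4595
    ring: 2.0
    COO: 0.7725
    COOH: 0.2725
notes: Repeat unit = two anhydroglucose rings with fractional methoxyl/hydroxypropyl/acetyl/succinoyl
  substitution pinned to reproduce the published parameters.
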