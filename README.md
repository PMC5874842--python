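# asdscreen

Early-stage screening of drug–polymer miscibility for amorphous solid
dispersions (ASDs), in Python.

When a poorly water-soluble drug is spray-dried into a polymer carrier, the
product may be a one-phase *glass solution* (the desirable state), an
amorphous but phase-separated mixture, or a dispersion with residual
crystallinity. `asdscreen` implements the standard in-silico screen for
picking carriers and drug loadings before any powder is made, plus the
analysis pipeline used to compare in-silico predictions with bench-scale
screening measurements:

* **Group-contribution solubility parameters** — Fedors
  (`δ = sqrt(ΣnᵢEᵢ / ΣnᵢVᵢ)`) and Hoftyzer–van Krevelen
  (`δd = ΣnᵢFdᵢ/V`, `δp = sqrt(ΣnᵢFpᵢ²)/V`, `δh = sqrt(ΣnᵢEhᵢ/V)`,
  `δtot² = δd² + δp² + δh²`), with copolymer repeat-unit averaging and
  bundled descriptors for four model drugs (ibuprofen, naproxen,
  carbamazepine, itraconazole) and seven pharmaceutical polymers.
* **Flory–Huggins thermodynamics** —
  `χ = 0.34 + v·Δδ²/(RT)`, free energy of mixing
  `ΔG/RT = φ ln φ + ((1−φ)/m) ln(1−φ) + χφ(1−φ)`, spinodal compositions
  from `1/φ + 1/(m(1−φ)) − 2χ = 0`, and classification of each pair as
  miscible in all proportions / partially miscible / bulk-immiscible.
* **Screening criteria** — the Greenhalgh rule (`Δδ < 7 MPa^½` favourable)
  and Bagley-plot distances in `(δv, δh)` space with
  `δv = sqrt(δd² + δp²)`.
* **Miscibility classification** of DSC/XRPD screening observations into
  A (glass solution), AA (amorphous phase separation), AC (residual
  crystallinity), honouring the ~10 °C resolution limit for neighbouring
  glass transitions.
* **Polymer ranking and concordance** — per-method top-3 polymer lists and
  their agreement with the spray-dryer reference as position-match (f1)
  and identity-match (f2) fractions.
* **Method comparison by PCA** on encoded class grids, thermal properties
  or concordance scores, with score-space distances from the reference.
* **Synthetic data** — seeded generators for modulated-DSC-like traces,
  powder diffractograms, and whole screening campaigns with planted
  miscibility boundaries and per-method biases, so every stage is testable
  with known ground truth.

## Worked example

```python
import asdscreen as asd

compounds = asd.load_all_compounds()
fedors = asd.load_bundled_table("fedors")

ibu = asd.compound_parameters(compounds["IBU"], fedors)
sol = asd.compound_parameters(compounds["SOL"], fedors)
print(round(ibu.delta_total, 1), round(ibu.molar_volume, 1))  # 20.9 195.5

chi = asd.chi_from_solubility(ibu.molar_volume, ibu.delta_total, sol.delta_total).chi
m = asd.lattice_ratio(asd.polymer_chain_volume(115000, 1.03), ibu.molar_volume)
diagram = asd.classify_profile(chi, m)
print(round(chi, 1), diagram.profile_class, round(diagram.phi_min, 3))
# 0.7 miscible_all_proportions 0.265
```

Ibuprofen's Fedors parameter is 20.9 MPa^½ at a molar volume of
195.5 cm³/mol; against Soluplus the interaction parameter is 0.7, the
mixing free energy is negative at every composition, and its minimum sits
at a drug volume fraction of 0.265 — below that loading the glass solution
is thermodynamically stable, above it supersaturated but amorphous.

The scripts in `examples/` walk through each capability (parameter tables,
phase diagrams, observation classification, a synthetic campaign with
ranking, concordance and PCA); each prints its results with a line on what
they mean. A thin CLI mirrors the library:

```bash
asdscreen delta -c IBU
asdscreen phase-diagram IBU SOL --out profile.tsv
asdscreen simulate --seed 7 --out obs.tsv && asdscreen classify obs.tsv
asdscreen run-all --seed 7 --out screen_out
```

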