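# Methods

This note documents the models implemented in `asdscreen`, the parameter
choices behind the bundled fixtures, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Solubility parameters by group contribution

Two classical estimation schemes are implemented over tab-separated
increment tables bundled with the package.

**Fedors.** Each structural group carries a cohesive energy `E` (J/mol) and
a molar-volume increment `V` (cm³/mol); the total solubility parameter is
`δ = sqrt(ΣnᵢEᵢ / ΣnᵢVᵢ)`. Because 1 cm³·MPa = 1 J, the ratio of J/mol to
cm³/mol is directly in MPa and δ in MPa^½. Negative volume increments
(tertiary/quaternary carbons, ring-junction nitrogens, the conjugation
correction) are branching corrections; the table loader rejects negative
volumes on any other group.

**Hoftyzer–van Krevelen.** The parameter is split into dispersive, polar
and hydrogen-bonding parts, `δd = ΣnᵢFdᵢ/V`, `δp = sqrt(ΣnᵢFpᵢ²)/V`,
`δh = sqrt(ΣnᵢEhᵢ/V)`, with `δtot` the quadrature of the three. The polar
convention multiplies each group's *squared* attraction constant by its
count (`nᵢ·Fpᵢ²`, not `(nᵢFpᵢ)²`). A direct consequence, asserted in the
test suite rather than papered over: δd and δh are invariant under
rescaling of the repeat unit while δp scales as `1/sqrt(k)` — the size of
a polymer repeat unit is model input, not a free normalisation. The
van Krevelen table reuses the Fedors molar volumes, the standard pairing
when the two schemes are used side by side; this choice is what makes the
bundled fixtures reproduce the published volume columns of both methods,
including their differences (the van Krevelen fragmentations omit the
condensed-aromatic and conjugation corrections that the Fedors table
provides, and split amides into N + C=O because the van Krevelen table has
no amide composites).

**Fragmentations.** The original study does not publish its group
fragmentations, so the bundled compound descriptors pin one fragmentation
per compound and method, chosen to be chemically sensible and to reproduce
the published parameter table. Ibuprofen is exact at printed precision
(3 CH₃ + 2 CH + CH₂ + p-phenylene + COOH → 20.9 MPa^½, 195.5 cm³/mol).
Two minor increments are pinned rather than literature-certain: the
azomethine ring-nitrogen volume (−2.7 cm³/mol; it lands both itraconazole
molar volumes simultaneously) and Fd = 1270 for a trisubstituted aromatic
ring. The hypromellose derivatives are modelled as two anhydroglucose
rings with fractional methoxyl/hydroxypropyl/phthalyl (HP50) or
methoxyl/hydroxypropyl/acetyl/succinoyl (HAS) substitution; commercial
grades span a range of substituent proportions, and the fixtures pin the
pattern (one per method) that reproduces the published values. Fractional
group counts are therefore legitimate throughout.

**Copolymers.** Two conventions are implemented. The default,
`parameter_average`, computes each repeat unit's parameters separately and
returns the mole-fraction-weighted mean of every parameter — components,
total, and molar volume alike. The alternative, `repeat_unit_average`,
averages the group counts into one hypothetical unit first. The default
was chosen because it is the convention the published copolymer values
follow (e.g. the printed PVPVA total equals the weighted mean of the unit
totals, 24.38, not the quadrature of the printed components, 24.25; the
Soluplus total is reproduced to 0.004 under parameter averaging and is 0.6
off under count averaging). A corollary: for parameter-averaged results
the quadrature identity `δtot² = δd²+δp²+δh²` holds only approximately;
such results are flagged (`averaged=True`) and the identity enforced
strictly only for single-unit computations.

## Flory–Huggins thermodynamics

The interaction parameter is estimated from solubility parameters as
`χ = 0.34 + v·Δδ²/(RT)` with `v` the drug molar volume (cm³/mol), Δδ in
MPa^½, R = 8.314 J/(mol·K) and T defaulting to 298.15 K (configurable).
The empirical 0.34 offset makes χ ≥ 0.34 by construction.

The mixing free energy per lattice site is
`ΔG/RT = φ ln φ + ((1−φ)/m) ln(1−φ) + χφ(1−φ)` with φ the drug volume
fraction. The lattice ratio `m` is the whole polymer chain volume (Mw/ρ
from the physical property table) over the drug molar volume from group
contributions; the per-repeat-unit alternative is available by passing a
different chain volume. With this convention the ibuprofen/Soluplus curve
(χ = 0.7, m ≈ 571) has its minimum at φ ≈ 0.265, consistent with the
reported "around 0.3" location.

Spinodal compositions solve `1/φ + 1/(m(1−φ)) − 2χ = 0`, algebraically the
quadratic `2χmφ² − (2χm + m − 1)φ + m = 0`; real roots in (0,1) exist iff
`χ ≥ (1 + 1/√m)²/2` (discriminant = 0). The closed form is verified in the
tests against an independent sign-change scan plus bisection on the second
derivative, to 1e-9 over 1000 random (χ, m) draws.

**Profile classification.** The curve is evaluated on 2001 points of
[1e-4, 1−1e-4] (endpoints excluded to avoid ln 0; the class is invariant
to refinement beyond ~10³ points, tested on all 28 bundled pairs). A pair
is `miscible_all_proportions` if ΔG < 0 on the whole grid and
`immiscible_bulk` if ΔG > 0 everywhere on [0.05, 0.95]. The dilute tails
are deliberately excluded from the bulk test: the ideal entropy term
forces ΔG < 0 as φ → 0 or 1 for *any* χ, so "positive at all proportions"
is only meaningful away from the tails. Everything else is
`partially_miscible`, with the critical composition located by sign-change
bracketing and Brent's method to 1e-10.

## Screening criteria

The Greenhalgh rule reads `Δδ < 7 MPa^½` (strict) as favourable; values at
or above 7 are flagged, matching the treatment of the one flagged pair in
the reference data (ibuprofen/HPMCP under van Krevelen). The criterion is
evaluated per method and both verdicts reported. Bagley coordinates
`(δv, δh)` with `δv = sqrt(δd²+δp²)` require van Krevelen components;
asking for them from Fedors parameters raises an error rather than
substituting silently.

## Miscibility classification

Observations carry glass-transition events (inflection temperature,
onset-to-end width), melting/recrystallization flags, a mesophase
endotherm count, and an X-ray crystallinity flag. Classification applies
three rules with precedence AC > AA > A:

1. **AC** — any crystallinity marker: sharp diffraction peaks, a melting
   endotherm, or a recrystallization exotherm.
2. **AA** — two or more glass transitions after merging events closer than
   the 10 °C instrument resolution (single-linkage, transitive,
   ΔCp-weighted mean when step heights are available), or a single
   transition within ±3 °C of a pure-component value; mesophase endotherms
   reinforce a drug-like transition but never count alone.
3. **A** — a single transition strictly between the pure-component values
   and beyond the tolerance of both.

The ±3 °C pure-component tolerance is configurable; the default is
motivated by the canonical worked case (a drug-like transition observed at
58.9 °C against a pure-drug value of 59 °C). A record with no transition
is a validation error; a single transition outside the interval spanned by
the pure components (± tolerance) raises an anomaly error — plasticization
by residual solvent is the usual cause and mislabelling would hide it.
Replicates are classified individually; the campaign-level class is the
modal label with ties resolved toward the less miscible class.

## Ranking and concordance

Experimental rankings order polymers by the highest drug loading achieving
a campaign-level class A (descending), with deterministic tie-breaks:
higher mixed-Tg at that loading, narrower transition width, alphabetical
abbreviation. Polymers with no glass solution rank after all that have
one, ordered by their best achieved class. Theoretical rankings sort one
score per polymer ascending (smaller Δδ, χ or Bagley distance = more
miscible), ties alphabetical.

Top-3 agreement with the reference is scored two ways: `f_position`
(fraction of the three rank positions holding the same polymer) and
`f_identity` (fraction of polymers shared irrespective of position);
`f_position ≤ f_identity` always. The reference tables label these f1 and
f2, but their caption wording ("polymer type" for f1) contradicts the
printed numbers, which uniquely identify f1 as the position score and f2
as the identity score across all 28 printed pairs; the code uses the
neutral names with f1/f2 as aliases and displays values as the
conventional truncated thirds (0, 0.33, 0.66, 1).

## Method comparison by PCA

Campaign class grids are encoded one row per method, one column per
(drug, polymer, loading) cell, ordinal A=2 > AA=1 > AC=0 — the classes
form a miscibility gradient, so an ordinal encoding is the default, with
one-hot available since the original encoding is unstated. Columns are
mean-centered and scaled to unit variance; zero-variance columns carry no
information and are dropped with a warning. The decomposition itself is
delegated to scikit-learn's PCA (full SVD); the wrapper fixes each
component's sign by making its largest-magnitude loading positive, so
results are backend-independent. Explained-variance ratios equal the
correlation-matrix eigenvalues over the column count (tested against an
independent eigendecomposition). The distance of each method's score
vector from the reference row replaces the visual reading of a score
plot. The published variance percentages for the original score plots are
not reproduced here: their input matrices derive from figure-only data
with an unstated layout, so the tests check decomposition properties and
planted-bias recovery instead.

## Synthetic data

The generator produces three artefact tiers, all deterministic per seed.

**Thermograms.** The reversing heat flow is a sum of logistic steps: the
analytic inflection point of each step sits at the specified transition
temperature, and the logistic scale is set so the 1–99% span equals the
specified onset-to-end width. The total heat flow adds Gaussian peaks
(melting and mesophase endotherms negative, recrystallization exotherms
positive) and i.i.d. Gaussian noise on a 0.1 °C grid over −90…300 °C.
The extractor smooths with a Savitzky–Golay filter, locates derivative
peaks, and reads the width as the span where the derivative exceeds 4% of
its local peak (the exact 1–99% correspondence for a logistic step).

**Diffractograms.** A broad Gaussian halo plus narrow Gaussian Bragg peaks
(default FWHM 0.1°) plus noise over 4.5–30° 2θ at 0.02° steps. The
crystallinity detector flags peaks whose prominence exceeds the limit of
detection with width at half-prominence under 0.5°.

**Campaigns.** Each (drug, polymer) pair has a planted maximum-miscible
drug loading; each preparation method an additive bias on that boundary
(defaults: quench cooling +0.2, room-temperature film casting −0.2,
reduced-pressure casting and the atomization-like method 0, the spray
dryer is the unbiased reference — the signs follow the qualitative field
finding that faster solvent removal and melt quenching over-predict the
miscibility of spray-dried material). Loadings at or below the shifted
boundary are class A and emit a single mixed glass transition placed by
the Fox rule `1/Tg_mix = w/Tg_drug + (1−w)/Tg_polymer` (in K) — used
purely as a plausible monotone interpolant, not a physical claim; loadings
within one 0.2-wide band above are AA and emit a drug-like plus a
polymer-like transition; anything beyond is AC with melting/diffraction
markers (plus recrystallization deep in the crystalline regime).
Transition temperatures carry Gaussian noise of sd 1.0 °C (typical
instrument repeatability; small against the 3 °C matching tolerance, so
noiseless recovery is exact and noisy recovery stays above 95%).
Optionally a fraction of AA samples draw amorphous domain sizes below the
30 nm detection limit (lognormal, median placed so the sub-limit
probability equals the requested fraction) and emit a single averaged
transition — ground truth the classifier cannot access, for honest
confusion accounting; the default fraction is 0 so that noiseless
recovery is exactly total.

What the generator does **not** emulate: enthalpy relaxation and
scan-rate-dependent DSC kinetics, baseline curvature, realistic peak
shapes or preferred orientation in diffraction, water uptake, or any
mechanistic link between process parameters and phase behaviour. Passing
tests on synthetic campaigns therefore demonstrate that the pipeline's
logic is correct under its own feature model, not that the feature model
captures every behaviour of real instruments.

## Numerical choices

* Free-energy grid 2001 points on [1e-4, 1−1e-4]; minimum polished with a
  bounded scalar search; critical composition by Brent bisection (1e-10).
* Spinodal roots from the quadratic closed form; empty when the
  discriminant is negative.
* Tg merging threshold 10 °C (strict inequality), match tolerance 3 °C,
  instrument range −90…300 °C.
* PCA sign fixed by the largest-|loading| rule; standardization uses the
  population standard deviation.
* Formatted outputs round parameters, differences, χ and distances to one
  decimal; raw-precision companion files are always written.

## Known limitations

* **Cellulose-ester polar components.** The published δp values of the two
  hypromellose esters (3.8 for the phthalate, 4.3 for the acetate
  succinate) cannot be reproduced from the standard hydroxyl (Fp = 500)
  and ether (Fp = 400) polar increments under *any* non-negative
  substitution pattern: with the molar volume pinned by the printed v and
  δh = 16.4/17.2 requiring several hydroxyls per repeat unit, δp has a
  structural floor near 4.1/4.5. Constrained minimax fits confirm the gap
  (~0.3/~0.2) cannot be traded away against the other columns, and the
  hydroxyl Fp values the printed δp would imply (359 and 434) are mutually
  inconsistent, so no alternative table value fixes both. The fixtures
  solve volume, δd and δh exactly and leave the irreducible error in δp;
  the corresponding two acceptance tests fail at the stated tolerance and
  are expected to.
* The bundled fragmentations reproduce the published parameter table but
  are not guaranteed to match the study's unpublished fragmentations
  group-for-group; downstream screening quantities recomputed from the
  *printed* parameters are unaffected.
* The Greenhalgh cutoff, the χ offset 0.34 and the Fox rule are empirical
  conventions, kept because the screening methodology is defined in terms
  of them; none is a physical law, and the package's comparisons of
  thermodynamic predictions with (synthetic) experimental outcomes
  illustrate exactly how loose these conventions can be.
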