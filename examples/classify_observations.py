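"""Miscibility classification of three itraconazole/PVP K30 measurements.

The three records mirror the canonical screening outcomes: a single mixed
glass transition (one-phase glass solution, A), a drug-like transition with
mesophase endotherms (amorphous phase separation, AA), and the same with a
recrystallization exotherm (residual crystallinity, AC).
"""

import asdscreen as asd
from asdscreen.classify import ObservationRecord, TgEvent, classify_observation

compounds = asd.load_all_compounds()
itr, pk30 = compounds["ITR"], compounds["PK30"]

cases = [
    ("40:60 spray-dried, single Tg at 110 degC",
     ObservationRecord(drug="ITR", polymer="PK30", drug_loading=0.4, method="SD",
                       tg_events=(TgEvent(110.0, 12.0),))),
    ("60:40 quench-cooled, Tg at 58.9 degC (pure drug) + mesophases",
     ObservationRecord(drug="ITR", polymer="PK30", drug_loading=0.6, method="QC",
                       tg_events=(TgEvent(58.9, 10.0),), mesophase_endotherms=2)),
    ("60:40 spray-dried, same + recrystallization on heating",
     ObservationRecord(drug="ITR", polymer="PK30", drug_loading=0.6, method="SD",
                       tg_events=(TgEvent(58.9, 10.0),), mesophase_endotherms=2,
                       recrystallization_detected=True)),
]

for label, obs in cases:
    result = classify_observation(obs, itr, pk30)
    print(f"{label}\n  -> class {result.label}  (rules fired: {', '.join(result.rationale)})\n")

print(
    "A = one-phase amorphous glass solution; AA = amorphous but phase-"
    "separated; AC = residual or re-forming crystallinity (least stable)."
)
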