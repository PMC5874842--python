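"""Miscibility classification of screening observations.

Each prepared dispersion is measured by modulated DSC (reversing signal for
glass transitions, total signal for melting/recrystallization) and by X-ray
powder diffraction, then assigned one of three classes:

* ``A``  -- ideal amorphous glass solution: a single mixed glass transition
  strictly between the pure-component values, no crystallinity;
* ``AA`` -- amorphous phase separation: two glass transitions, or a single
  transition sitting at a pure-component value (a drug-rich phase whose
  polymer-rich counterpart escaped detection), optionally accompanied by
  mesophase endotherms of the glassy drug;
* ``AC`` -- residual crystallinity: a melting endotherm, a recrystallization
  exotherm, or sharp diffraction peaks.

Precedence is AC > AA > A: any crystallinity marker wins, then any
phase-separation marker.  The instrument cannot resolve two transitions
closer than ~10 degC, so events are merged at that resolution before the
rules fire; sub-resolution phase structure is never inferred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .constants import TG_MATCH_TOL_C, TG_RESOLUTION_C
from .errors import AnomalousObservationError, ValidationError
from .groups import CompoundDescriptor

ClassLabel = Literal["A", "AA", "AC"]
PreparationMethod = Literal["FC_RT", "FC_RP", "QC", "AD", "SD"]
METHOD_IDS: tuple[str, ...] = ("FC_RT", "FC_RP", "QC", "AD", "SD")
METHOD_LABELS = {
    "FC_RT": "film casting, room temperature",
    "FC_RP": "film casting, reduced pressure",
    "QC": "quench cooling",
    "AD": "atomization device",
    "SD": "spray dryer",
}

#: Miscibility ordering used for conservative tie resolution (lower = worse).
CLASS_ORDER: dict[str, int] = {"AC": 0, "AA": 1, "A": 2}

_INSTRUMENT_RANGE_C = (-90.0, 300.0)


@dataclass(frozen=True)
class TgEvent:
    """One glass-transition step: inflection temperature and onset-to-end
    width, both in degC; optional step height (heat-capacity change)."""

    value: float
    width: float
    height: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("Tg width must be positive")
        lo, hi = _INSTRUMENT_RANGE_C
        if not lo <= self.value <= hi:
            raise ValidationError(
                f"Tg {self.value} degC outside instrument range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class ObservationRecord:
    """One screening measurement of one dispersion."""

    drug: str
    polymer: str
    drug_loading: float
    method: str
    tg_events: tuple[TgEvent, ...] = ()
    melting_detected: bool = False
    recrystallization_detected: bool = False
    mesophase_endotherms: int = 0
    xrpd_crystalline: bool = False
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.drug_loading < 1.0:
            raise ValidationError("drug loading must be a mass fraction in (0, 1)")
        if self.method not in METHOD_IDS:
            raise ValidationError(f"unknown preparation method {self.method!r}")
        if self.mesophase_endotherms < 0:
            raise ValidationError("mesophase endotherm count must be non-negative")


@dataclass(frozen=True)
class MiscibilityClass:
    """Assigned label plus the machine-readable list of rules that fired."""

    label: ClassLabel
    rationale: tuple[str, ...] = field(default_factory=tuple)


def merge_unresolvable_tgs(
    events: Sequence[TgEvent], resolution: float = TG_RESOLUTION_C
) -> tuple[TgEvent, ...]:
    """Merge glass transitions closer than the instrument resolution.

    Merging is transitive (single-linkage): a chain of events each within
    ``resolution`` of the next collapses to one event at the height-weighted
    (unweighted if heights are absent) mean, with a width spanning the union
    of the member transition regions.  Idempotent, order-insensitive.
    """
    if not events:
        return ()
    ordered = sorted(events, key=lambda e: e.value)
    clusters: list[list[TgEvent]] = [[ordered[0]]]
    for ev in ordered[1:]:
        if ev.value - clusters[-1][-1].value < resolution:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    merged = []
    for cluster in clusters:
        if len(cluster) == 1:
            merged.append(cluster[0])
            continue
        if all(e.height is not None for e in cluster):
            wsum = sum(e.height for e in cluster)  # type: ignore[misc]
            center = sum(e.value * e.height for e in cluster) / wsum  # type: ignore[operator]
            height: float | None = wsum
        else:
            center = sum(e.value for e in cluster) / len(cluster)
            height = None
        lo = min(e.value - e.width / 2 for e in cluster)
        hi = max(e.value + e.width / 2 for e in cluster)
        merged.append(TgEvent(value=center, width=hi - lo, height=height))
    return tuple(merged)


def classify_observation(
    obs: ObservationRecord,
    pure_drug: CompoundDescriptor,
    pure_polymer: CompoundDescriptor,
    tol: float = TG_MATCH_TOL_C,
    resolution: float = TG_RESOLUTION_C,
) -> MiscibilityClass:
    """Assign a miscibility class to one observation.

    Rules in precedence order (AC > AA > A):

    1. any crystallinity marker (diffraction peaks, melting endotherm,
       recrystallization exotherm) -> AC;
    2. two or more resolved glass transitions, or a single transition
       within ``tol`` of a pure-component value (with or without mesophase
       endotherms) -> AA;
    3. a single transition strictly between the pure values and beyond
       ``tol`` of both -> A.

    A record with no glass transition at all cannot be interpreted
    (ValidationError); a single transition outside the interval spanned by
    the pure components (minus/plus ``tol``) suggests plasticization and
    raises :class:`AnomalousObservationError` rather than mislabelling.
    """
    fired: list[str] = []
    if obs.xrpd_crystalline:
        fired.append("xrpd_sharp_peaks")
    if obs.melting_detected:
        fired.append("melting_endotherm")
    if obs.recrystallization_detected:
        fired.append("recrystallization_exotherm")
    if fired:
        return MiscibilityClass(label="AC", rationale=tuple(fired))

    events = merge_unresolvable_tgs(obs.tg_events, resolution=resolution)
    if not events:
        raise ValidationError(
            f"{obs.drug}/{obs.polymer} {obs.method}: no glass transition detected; "
            "record cannot be classified"
        )

    tg_lo, tg_hi = sorted((pure_drug.tg_c, pure_polymer.tg_c))
    if len(events) >= 2:
        return MiscibilityClass(label="AA", rationale=("multiple_tg",))

    tg = events[0].value
    near_drug = abs(tg - pure_drug.tg_c) <= tol
    near_polymer = abs(tg - pure_polymer.tg_c) <= tol
    if near_drug or near_polymer:
        fired = ["tg_at_pure_component"]
        if obs.mesophase_endotherms > 0 and near_drug:
            fired.append("mesophase_endotherms_with_drug_tg")
        return MiscibilityClass(label="AA", rationale=tuple(fired))

    if tg < tg_lo - tol or tg > tg_hi + tol:
        raise AnomalousObservationError(
            f"{obs.drug}/{obs.polymer} {obs.method}: single Tg at {tg:.1f} degC lies "
            f"outside [{tg_lo - tol:.1f}, {tg_hi + tol:.1f}] degC; plasticization "
            "(e.g. residual solvent) suspected"
        )
    return MiscibilityClass(label="A", rationale=("single_mixed_tg",))


def modal_class(labels: Sequence[ClassLabel]) -> ClassLabel:
    """Campaign-level class across replicates: the modal label, with ties
    resolved toward the less miscible class (conservative)."""
    if not labels:
        raise ValidationError("no replicate classes to aggregate")
    counts = Counter(labels)
    best = max(counts.values())
    tied = [lab for lab, n in counts.items() if n == best]
    return min(tied, key=lambda lab: CLASS_ORDER[lab])


def classify_campaign(
    records: Sequence[ObservationRecord],
    compounds: dict[str, CompoundDescriptor],
    tol: float = TG_MATCH_TOL_C,
    resolution: float = TG_RESOLUTION_C,
) -> dict[tuple[str, str, float, str], ClassLabel]:
    """Classify every record and aggregate replicates per condition.

    Returns a mapping ``(drug, polymer, drug_loading, method) -> label``.
    """
    per_condition: dict[tuple[str, str, float, str], list[ClassLabel]] = {}
    for obs in records:
        label = classify_observation(
            obs, compounds[obs.drug], compounds[obs.polymer], tol=tol, resolution=resolution
        ).label
        key = (obs.drug, obs.polymer, obs.drug_loading, obs.method)
        per_condition.setdefault(key, []).append(label)
    return {key: modal_class(labels) for key, labels in per_condition.items()}


def with_replicate(obs: ObservationRecord, replicate: int) -> ObservationRecord:
    """Copy of a record with a different replicate index."""
    return replace(obs, replicate=replicate)
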