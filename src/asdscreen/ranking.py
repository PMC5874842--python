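"""Polymer rank orders and their agreement with a reference method.

An experimental ranking orders polymers by their ability to deliver glass
solutions (class A) at high drug loading; theoretical rankings order them
by ascending interaction scores (smaller solubility-parameter difference,
Flory-Huggins chi, or Bagley distance = more miscible).  Agreement between
a predicted top-3 list and the reference (spray-dryer) top-3 is scored by
two fractions:

* ``f_position`` (alias ``f1``): fraction of the three rank positions
  holding the same polymer in both lists;
* ``f_identity`` (alias ``f2``): fraction of the three polymers shared by
  the two lists regardless of position.

``f_position <= f_identity`` always.  Values are conventionally displayed
as 0 / 0.33 / 0.66 / 1 (two-decimal truncation of thirds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .classify import CLASS_ORDER, ClassLabel
from .errors import ValidationError

RankingBasis = Literal["max_DL_glass_solution", "delta_asc", "chi_asc", "euclidean_asc"]


@dataclass(frozen=True)
class PolymerRanking:
    """An ordered list of polymers for one drug under one method."""

    drug: str
    method: str
    polymers: tuple[str, ...]
    basis: RankingBasis
    tie_breaks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.polymers:
            raise ValidationError("ranking must contain at least one polymer")
        if len(set(self.polymers)) != len(self.polymers):
            raise ValidationError("ranking contains duplicate polymers")

    def top(self, k: int = 3) -> tuple[str, ...]:
        return self.polymers[:k]


@dataclass(frozen=True)
class ConcordanceScores:
    """Top-k agreement between a predicted and a reference ranking."""

    f_position: float
    f_identity: float
    k: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_position <= self.f_identity <= 1.0:
            raise ValidationError("scores must satisfy 0 <= f_position <= f_identity <= 1")

    # The published tables call the position score f1 and the identity
    # score f2; expose those names as aliases.
    @property
    def f1(self) -> float:
        return self.f_position

    @property
    def f2(self) -> float:
        return self.f_identity

    @staticmethod
    def format_thirds(value: float) -> str:
        """Display a multiple of 1/3 as 0, 0.33, 0.66 or 1 (truncated)."""
        thirds = round(value * 3)
        return {0: "0", 1: "0.33", 2: "0.66", 3: "1"}[thirds]


@dataclass(frozen=True)
class PolymerOutcome:
    """Per-polymer summary feeding the experimental ranking."""

    polymer: str
    best_class: ClassLabel
    max_loading_class_a: float | None
    tg_at_best: float | None = None
    tg_width_at_best: float | None = None


def rank_experimental(
    drug: str,
    method: str,
    outcomes: Sequence[PolymerOutcome],
) -> PolymerRanking:
    """Rank polymers by glass-solution performance at high drug loading.

    Primary key: highest drug loading at which the campaign-level class is
    A (descending); polymers with no class-A record rank after all that
    have one, ordered by their best achieved class (AA before AC).
    Tie-breaks, in order: higher mixed-Tg value at the best loading,
    narrower Tg width, alphabetical abbreviation.  Deterministic.
    """
    if not outcomes:
        raise ValidationError("no polymer outcomes to rank")
    trail: list[str] = []

    def key(o: PolymerOutcome):
        has_a = o.max_loading_class_a is not None
        return (
            0 if has_a else 1,
            -(o.max_loading_class_a or 0.0),
            -CLASS_ORDER[o.best_class],
            -(o.tg_at_best if o.tg_at_best is not None else float("-inf")),
            o.tg_width_at_best if o.tg_width_at_best is not None else float("inf"),
            o.polymer,
        )

    ordered = sorted(outcomes, key=key)
    for a, b in zip(ordered, ordered[1:]):
        if key(a)[:2] == key(b)[:2]:
            trail.append(f"{a.polymer}>{b.polymer}: tie at DL broken by Tg/width/name")
    return PolymerRanking(
        drug=drug,
        method=method,
        polymers=tuple(o.polymer for o in ordered),
        basis="max_DL_glass_solution",
        tie_breaks=tuple(trail),
    )


def rank_theoretical(
    drug: str,
    method: str,
    scores: Mapping[str, float],
    basis: RankingBasis,
) -> PolymerRanking:
    """Rank polymers by ascending interaction score (smaller = better).

    Ties are broken alphabetically by abbreviation.
    """
    if not scores:
        raise ValidationError("no scores to rank")
    for polymer, score in scores.items():
        if score is None:
            raise ValidationError(f"missing score for polymer {polymer!r}")
    ordered = sorted(scores, key=lambda p: (scores[p], p))
    ties = [
        f"{a}>{b}: equal score, alphabetical"
        for a, b in zip(ordered, ordered[1:])
        if scores[a] == scores[b]
    ]
    return PolymerRanking(
        drug=drug, method=method, polymers=tuple(ordered), basis=basis,
        tie_breaks=tuple(ties),
    )


def concordance(
    predicted: Sequence[str], reference: Sequence[str], k: int = 3
) -> ConcordanceScores:
    """Score a predicted top-k polymer list against a reference list.

    ``f_position`` counts same-position matches; ``f_identity`` counts
    shared polymers irrespective of position.
    """
    if len(predicted) != k or len(reference) != k:
        raise ValidationError(f"both lists must have exactly {k} entries")
    if len(set(predicted)) != k or len(set(reference)) != k:
        raise ValidationError("ranking lists must be duplicate-free")
    position = sum(p == r for p, r in zip(predicted, reference)) / k
    identity = len(set(predicted) & set(reference)) / k
    return ConcordanceScores(f_position=position, f_identity=identity, k=k)
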