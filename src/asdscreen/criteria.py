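"""Quick screening criteria: Greenhalgh difference and Bagley-plot distance.

The Greenhalgh criterion reads a solubility-parameter difference below
7 MPa^1/2 as favourable mixing.  The Bagley plot projects compounds onto
``(delta_v, delta_h)`` with ``delta_v = sqrt(delta_d^2 + delta_p^2)``;
small Euclidean distances between a drug and a polymer suggest similar
dispersive/polar and hydrogen-bonding character, hence miscibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .constants import GREENHALGH_CUTOFF
from .errors import DomainError, UnsupportedMethodError
from .groups import SolubilityParameters

Verdict = Literal["favorable", "borderline_or_unfavorable"]


@dataclass(frozen=True)
class BagleyPoint:
    """A compound's coordinates in the Bagley diagram (MPa^1/2)."""

    compound: str
    delta_v: float
    delta_h: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_v) and math.isfinite(self.delta_h)):
            raise DomainError("Bagley coordinates must be finite")


@dataclass(frozen=True)
class CriterionResult:
    """Greenhalgh difference and verdict for one pair."""

    drug: str
    polymer: str
    delta_difference: float
    verdict: Verdict


def greenhalgh(
    delta_drug: float, delta_polymer: float, cutoff: float = GREENHALGH_CUTOFF
) -> tuple[float, Verdict]:
    """Absolute solubility-parameter difference and its reading.

    The comparison is strict: differences at or above the cutoff are
    flagged as indicating some degree of immiscibility.
    """
    if not (math.isfinite(delta_drug) and math.isfinite(delta_polymer)):
        raise DomainError("solubility parameters must be finite")
    diff = abs(delta_drug - delta_polymer)
    verdict: Verdict = "favorable" if diff < cutoff else "borderline_or_unfavorable"
    return diff, verdict


def bagley_point(params: SolubilityParameters, compound: str = "") -> BagleyPoint:
    """Project van Krevelen components onto the Bagley plane.

    Fedors parameters carry no dispersive/polar split, so asking for their
    Bagley coordinates is an error rather than a silent substitution.
    """
    if not params.has_components:
        raise UnsupportedMethodError(
            "Bagley coordinates require van Krevelen components; "
            f"got method {params.method_id!r}"
        )
    return BagleyPoint(compound=compound, delta_v=params.delta_v, delta_h=params.delta_h)


def bagley_distance(a: BagleyPoint, b: BagleyPoint) -> float:
    """Euclidean distance between two compounds in the Bagley plane."""
    return math.hypot(a.delta_v - b.delta_v, a.delta_h - b.delta_h)
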