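"""Flory-Huggins mixing thermodynamics for drug-polymer pairs.

The free energy of mixing per lattice site (in units of RT) is

    dG(phi) = phi ln(phi) + (1 - phi)/m * ln(1 - phi) + chi * phi * (1 - phi)

where ``phi`` is the drug volume fraction, ``m`` the ratio of polymer-chain
volume to lattice-site volume (the drug molar volume is used as the lattice
site), and ``chi`` the interaction parameter.  ``chi`` is estimated from
solubility parameters as

    chi = 0.34 + v_drug * (delta_drug - delta_polymer)**2 / (R T)

The spinodal (limit of stability) is where the second composition
derivative vanishes:

    1/phi + 1/(m (1 - phi)) - 2 chi = 0

which is the quadratic ``2 chi m phi^2 - (2 chi m + m - 1) phi + m = 0``;
real roots in (0,1) exist iff ``chi >= (1 + 1/sqrt(m))**2 / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .constants import CHI_EMPIRICAL_OFFSET, R_GAS, T_AMBIENT_K
from .errors import DomainError, ValidationError

ProfileClass = Literal["miscible_all_proportions", "partially_miscible", "immiscible_bulk"]

#: Dilute tails excluded when judging bulk immiscibility: the ideal entropy
#: term forces dG < 0 as phi -> 0 or 1 no matter how unfavourable chi is, so
#: "positive at all proportions" is assessed on [0.05, 0.95] only.
_BULK_WINDOW = (0.05, 0.95)


@dataclass(frozen=True)
class EnvironmentConstants:
    """Thermodynamic environment: gas constant, temperature, chi offset."""

    temperature_k: float = T_AMBIENT_K
    gas_constant: float = R_GAS
    empirical_offset: float = CHI_EMPIRICAL_OFFSET

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValidationError("temperature must be positive (K)")


@dataclass(frozen=True)
class PairInteraction:
    """Interaction estimate for one drug-polymer pair under one method."""

    drug: str
    polymer: str
    method_id: str
    delta_difference: float
    chi: float
    temperature_k: float


@dataclass(frozen=True)
class PhaseDiagram:
    """Free-energy-of-mixing profile over composition with its summary.

    ``phi_min`` is the composition of minimum dG/RT (None when the curve is
    non-negative throughout the grid), ``phi_critical`` the first crossing
    from negative to positive free energy (None when no crossing), and
    ``spinodal`` the 0-2 roots of the stability condition.
    """

    chi: float
    m: float
    phi: np.ndarray
    delta_g: np.ndarray
    phi_min: float | None
    phi_critical: float | None
    spinodal: tuple[float, ...]
    profile_class: ProfileClass

    def __post_init__(self) -> None:
        if self.phi.min() <= 0 or self.phi.max() >= 1:
            raise ValidationError("composition grid must lie strictly inside (0, 1)")
        if not np.all(np.isfinite(self.delta_g)):
            raise ValidationError("free-energy values must be finite")
        if list(self.spinodal) != sorted(self.spinodal):
            raise ValidationError("spinodal roots must be ascending")


def chi_from_solubility(
    v_drug: float,
    delta_drug: float,
    delta_polymer: float,
    env: EnvironmentConstants | None = None,
    drug: str = "drug",
    polymer: str = "polymer",
    method_id: str = "fedors",
) -> PairInteraction:
    """Estimate chi from the solubility-parameter difference.

    ``v_drug`` in cm^3/mol and deltas in MPa^1/2 give the enthalpic term
    directly in J/mol (1 cm^3 MPa = 1 J); symmetric in the two deltas.
    """
    env = env or EnvironmentConstants()
    if v_drug <= 0:
        raise DomainError("drug molar volume must be positive")
    if not (math.isfinite(delta_drug) and math.isfinite(delta_polymer)):
        raise DomainError("solubility parameters must be finite")
    diff = abs(delta_drug - delta_polymer)
    chi = env.empirical_offset + v_drug * diff**2 / (env.gas_constant * env.temperature_k)
    return PairInteraction(
        drug=drug,
        polymer=polymer,
        method_id=method_id,
        delta_difference=diff,
        chi=chi,
        temperature_k=env.temperature_k,
    )


def lattice_ratio(polymer_chain_volume: float, v_drug: float) -> float:
    """Polymer chain volume over lattice-site (drug molar) volume."""
    if polymer_chain_volume <= 0 or v_drug <= 0:
        raise DomainError("volumes must be positive")
    return polymer_chain_volume / v_drug


def gibbs_mixing(phi, chi: float, m: float):
    """dG_mix/RT at drug volume fraction ``phi`` (scalar or array).

    Vanishes at both composition limits; for chi = 0 it is strictly
    negative on (0, 1).
    """
    phi_arr = np.asarray(phi, dtype=float)
    if m <= 0:
        raise DomainError("lattice ratio m must be positive")
    if np.any(phi_arr <= 0) or np.any(phi_arr >= 1):
        raise DomainError("phi must lie in the open interval (0, 1)")
    out = (
        phi_arr * np.log(phi_arr)
        + (1.0 - phi_arr) / m * np.log(1.0 - phi_arr)
        + chi * phi_arr * (1.0 - phi_arr)
    )
    return out.item() if np.isscalar(phi) or np.ndim(phi) == 0 else out


def critical_chi(m: float) -> float:
    """Smallest chi at which an unstable (spinodal) region exists."""
    if m <= 0:
        raise DomainError("lattice ratio m must be positive")
    return 0.5 * (1.0 + 1.0 / math.sqrt(m)) ** 2


def spinodal_compositions(chi: float, m: float) -> tuple[float, ...]:
    """Real spinodal roots in (0, 1), ascending (empty tuple if none).

    Solves ``2 chi m phi^2 - (2 chi m + m - 1) phi + m = 0``, the polynomial
    form of the vanishing second derivative of dG/RT.
    """
    if chi <= 0 or m <= 0:
        raise DomainError("chi and m must be positive")
    a = 2.0 * chi * m
    b = -(2.0 * chi * m + m - 1.0)
    c = m
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return ()
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    return tuple(r for r in roots if 0.0 < r < 1.0)


def classify_profile(
    chi: float,
    m: float,
    n_points: int = 2001,
    phi_margin: float = 1e-4,
) -> PhaseDiagram:
    """Evaluate the mixing free energy on a grid and classify its profile.

    Classes:

    * ``miscible_all_proportions`` -- dG < 0 over the whole grid;
    * ``immiscible_bulk`` -- dG > 0 everywhere on [0.05, 0.95] (the dilute
      tails, where entropy forces dG < 0 mathematically, are ignored);
    * ``partially_miscible`` -- anything in between: a negative branch up to
      a critical composition where demixing sets in.
    """
    if n_points < 101:
        raise ValidationError("grid resolution must be at least 101 points")
    phi = np.linspace(phi_margin, 1.0 - phi_margin, n_points)
    dg = gibbs_mixing(phi, chi, m)

    phi_min = None
    i_min = int(np.argmin(dg))
    if dg[i_min] < 0:
        # polish the grid argmin with a local parabolic/bounded search
        lo = phi[max(i_min - 1, 0)]
        hi = phi[min(i_min + 1, n_points - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda p: gibbs_mixing(p, chi, m), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        phi_min = float(res.x)

    phi_critical = None
    sign_change = np.nonzero((dg[:-1] < 0) & (dg[1:] >= 0))[0]
    if sign_change.size:
        i = int(sign_change[0])
        if dg[i + 1] == 0:
            phi_critical = float(phi[i + 1])
        else:
            phi_critical = float(
                brentq(lambda p: gibbs_mixing(p, chi, m), phi[i], phi[i + 1], xtol=1e-10)
            )

    lo, hi = _BULK_WINDOW
    bulk = dg[(phi >= lo) & (phi <= hi)]
    if np.all(dg < 0):
        profile: ProfileClass = "miscible_all_proportions"
    elif np.all(bulk > 0):
        profile = "immiscible_bulk"
    else:
        profile = "partially_miscible"

    return PhaseDiagram(
        chi=chi,
        m=m,
        phi=phi,
        delta_g=dg,
        phi_min=phi_min,
        phi_critical=phi_critical,
        spinodal=spinodal_compositions(chi, m) if chi > 0 else (),
        profile_class=profile,
    )
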