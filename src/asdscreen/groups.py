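"""Group-contribution estimation of solubility parameters and molar volumes.

Two classical schemes are implemented:

* **Fedors**: every structural group carries a cohesive energy ``E`` (J/mol)
  and a molar-volume increment ``V`` (cm^3/mol); the total solubility
  parameter is ``delta = sqrt(sum(n_i E_i) / sum(n_i V_i))`` in MPa^1/2.

* **Hoftyzer-van Krevelen**: the parameter is split into dispersive, polar
  and hydrogen-bonding components::

      delta_d = sum(n_i Fd_i) / V
      delta_p = sqrt(sum(n_i Fp_i**2)) / V
      delta_h = sqrt(sum(n_i Eh_i) / V)

  with ``V = sum(n_i V_i)``.  Note the polar convention: each group's
  *squared* attraction constant is multiplied by its count
  (``n_i * Fp_i**2``), **not** ``(n_i * Fp_i)**2``.  As a consequence
  ``delta_p`` is not invariant under rescaling of the repeat unit: doubling
  every count leaves ``delta_d`` and ``delta_h`` unchanged but divides
  ``delta_p`` by sqrt(2).  The size of a polymer repeat unit is therefore
  part of the model input, not a free normalisation.

Polymer parameters are computed per structural repeat unit.  For copolymers
the repeat-unit ratio enters the calculation; see
:func:`copolymer_parameters`.  The molar volume of a whole polymer chain
(molecular weight over true density) is a separate quantity used only for
the Flory-Huggins lattice ratio; see :func:`polymer_chain_volume`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import yaml

from .errors import (
    ConfigurationError,
    DomainError,
    UnknownGroupError,
    UnsupportedMethodError,
    ValidationError,
)

MethodId = Literal["fedors", "van_krevelen"]
METHODS: tuple[str, ...] = ("fedors", "van_krevelen")

#: Groups whose molar-volume increment is legitimately negative
#: (branching and ring-junction corrections).
_BRANCHING_GROUPS = frozenset({"CH", "C", "=C<", "N", "N=", "CON<", "conjugation"})

_QUADRATURE_TOL = 1e-9


@dataclass(frozen=True)
class FedorsEntry:
    """Cohesive energy (J/mol) and molar volume (cm^3/mol) of one group."""

    cohesive_energy: float
    molar_volume: float


@dataclass(frozen=True)
class VanKrevelenEntry:
    """Dispersive/polar attraction constants ((J cm^3)^1/2 / mol),
    hydrogen-bond cohesive energy (J/mol) and molar volume (cm^3/mol)."""

    f_dispersive: float
    f_polar: float
    e_hydrogen: float
    molar_volume: float


@dataclass(frozen=True)
class GroupContributionTable:
    """A named set of group increments for one estimation method."""

    method_id: str
    entries: Mapping[str, FedorsEntry | VanKrevelenEntry]

    def __post_init__(self) -> None:
        if self.method_id not in METHODS:
            raise ConfigurationError(f"unknown method {self.method_id!r}")
        for label, entry in self.entries.items():
            if entry.molar_volume < 0 and label not in _BRANCHING_GROUPS:
                raise ValidationError(
                    f"group {label!r} has negative molar volume but is not a "
                    "designated branching/ring-junction correction"
                )
            if isinstance(entry, VanKrevelenEntry):
                if entry.f_polar < 0 or entry.e_hydrogen < 0:
                    raise ValidationError(f"group {label!r}: Fp and Eh must be non-negative")

    def __getitem__(self, label: str):
        try:
            return self.entries[label]
        except KeyError:
            raise UnknownGroupError(label, self.method_id) from None


@dataclass(frozen=True)
class SolubilityParameters:
    """Solubility parameters (MPa^1/2) and molar volume (cm^3/mol).

    ``delta_d``/``delta_p``/``delta_h`` are populated only for the
    van Krevelen method; ``delta_v = sqrt(delta_d**2 + delta_p**2)`` is the
    combined dispersive/polar coordinate of the Bagley plot.

    For a single repeat unit the total obeys
    ``delta_total**2 == delta_d**2 + delta_p**2 + delta_h**2`` exactly.  For
    copolymers under the parameter-averaging convention each parameter --
    including the total -- is a mole-fraction-weighted mean of the unit
    values, and a mean of totals is not the quadrature of the means; such
    results carry ``averaged=True`` and the identity is only enforced
    loosely for them.
    """

    method_id: str
    delta_total: float
    molar_volume: float
    delta_d: float | None = None
    delta_p: float | None = None
    delta_h: float | None = None
    averaged: bool = False

    def __post_init__(self) -> None:
        values = [self.delta_total, self.molar_volume]
        if self.has_components:
            values += [self.delta_d, self.delta_p, self.delta_h]
        if not all(math.isfinite(v) and v >= 0 for v in values):  # type: ignore[arg-type]
            raise ValidationError("solubility parameters must be finite and non-negative")
        if self.has_components:
            quad = math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)
            tol = 0.5 if self.averaged else _QUADRATURE_TOL * max(1.0, self.delta_total)
            if abs(quad - self.delta_total) > tol:
                raise ValidationError(
                    "delta_total inconsistent with sqrt(delta_d^2+delta_p^2+delta_h^2)"
                )

    @property
    def has_components(self) -> bool:
        return self.delta_d is not None

    @property
    def delta_v(self) -> float:
        """Combined dispersive-polar parameter, sqrt(delta_d^2 + delta_p^2)."""
        if not self.has_components:
            raise UnsupportedMethodError(
                "delta_v requires van Krevelen components; the Fedors method "
                "provides only the total parameter"
            )
        return math.sqrt(self.delta_d**2 + self.delta_p**2)  # type: ignore[operator]


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit of a (co)polymer with its mole fraction."""

    name: str
    fraction: float
    group_counts: Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class CompoundDescriptor:
    """A drug or polymer described by structural group counts.

    ``group_counts`` maps method id to a ``label -> count`` mapping; counts
    may be fractional (copolymer-averaged or substitution-averaged repeat
    units).  For copolymers ``repeat_units`` carries the per-unit counts and
    mole fractions and takes precedence over ``group_counts``.
    """

    name: str
    abbreviation: str
    role: Literal["drug", "polymer"]
    mw: float
    tg_c: float
    group_counts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tm_c: float | None = None
    true_density: float | None = None
    gfa_class: Literal["I", "II", "III"] | None = None
    repeat_units: Sequence[RepeatUnit] | None = None
    notes: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("drug", "polymer"):
            raise ValidationError(f"role must be drug or polymer, got {self.role!r}")
        if self.mw <= 0:
            raise ValidationError("Mw must be positive")
        if self.true_density is not None and self.true_density <= 0:
            raise ValidationError("true density must be positive")
        if self.gfa_class not in (None, "I", "II", "III"):
            raise ValidationError(f"unknown GFA class {self.gfa_class!r}")
        for method, counts in self.group_counts.items():
            if any(c < 0 for c in counts.values()):
                raise ValidationError(f"{self.abbreviation}: negative group count ({method})")
        if self.repeat_units is not None:
            total = sum(u.fraction for u in self.repeat_units)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.abbreviation}: repeat-unit fractions sum to {total}, expected 1"
                )

    def counts_for(self, method_id: str) -> Mapping[str, float]:
        try:
            return self.group_counts[method_id]
        except KeyError:
            raise ConfigurationError(
                f"{self.abbreviation} has no group counts for method {method_id!r}"
            ) from None


def _sum_counts(
    group_counts: Mapping[str, float], table: GroupContributionTable
) -> list[tuple[float, FedorsEntry | VanKrevelenEntry]]:
    if not any(c > 0 for c in group_counts.values()):
        raise DomainError("at least one group must have a positive count")
    if any(c < 0 for c in group_counts.values()):
        raise DomainError("group counts must be non-negative")
    return [(count, table[label]) for label, count in group_counts.items()]


def fedors_parameters(
    group_counts: Mapping[str, float], table: GroupContributionTable
) -> SolubilityParameters:
    """Total solubility parameter and molar volume by the Fedors method.

    ``delta = sqrt(sum(n_i E_i) / sum(n_i V_i))``; with E in J/mol and V in
    cm^3/mol the ratio is in J/cm^3 = MPa, so delta is in MPa^1/2 directly.
    """
    if table.method_id != "fedors":
        raise ConfigurationError("fedors_parameters requires a Fedors table")
    pairs = _sum_counts(group_counts, table)
    energy = sum(n * e.cohesive_energy for n, e in pairs)  # type: ignore[union-attr]
    volume = sum(n * e.molar_volume for n, e in pairs)
    if volume <= 0:
        raise DomainError(f"total molar volume must be positive, got {volume:.3f} cm^3/mol")
    return SolubilityParameters(
        method_id="fedors",
        delta_total=math.sqrt(energy / volume),
        molar_volume=volume,
    )


def van_krevelen_parameters(
    group_counts: Mapping[str, float], table: GroupContributionTable
) -> SolubilityParameters:
    """Three-component solubility parameters by Hoftyzer-van Krevelen.

    The polar term sums *squared* attraction constants weighted by count
    (``n_i * Fp_i**2``); see the module docstring for the resulting
    repeat-unit-size dependence of ``delta_p``.
    """
    if table.method_id != "van_krevelen":
        raise ConfigurationError("van_krevelen_parameters requires a van Krevelen table")
    pairs = _sum_counts(group_counts, table)
    volume = sum(n * e.molar_volume for n, e in pairs)
    if volume <= 0:
        raise DomainError(f"total molar volume must be positive, got {volume:.3f} cm^3/mol")
    f_d = sum(n * e.f_dispersive for n, e in pairs)  # type: ignore[union-attr]
    f_p2 = sum(n * e.f_polar**2 for n, e in pairs)  # type: ignore[union-attr]
    e_h = sum(n * e.e_hydrogen for n, e in pairs)  # type: ignore[union-attr]
    delta_d = max(f_d, 0.0) / volume
    delta_p = math.sqrt(f_p2) / volume
    delta_h = math.sqrt(e_h / volume)
    return SolubilityParameters(
        method_id="van_krevelen",
        delta_total=math.sqrt(delta_d**2 + delta_p**2 + delta_h**2),
        molar_volume=volume,
        delta_d=delta_d,
        delta_p=delta_p,
        delta_h=delta_h,
    )


def single_unit_parameters(
    group_counts: Mapping[str, float], table: GroupContributionTable
) -> SolubilityParameters:
    """Dispatch to the appropriate single-unit calculation for ``table``."""
    if table.method_id == "fedors":
        return fedors_parameters(group_counts, table)
    return van_krevelen_parameters(group_counts, table)


CopolymerMode = Literal["parameter_average", "repeat_unit_average"]


def copolymer_parameters(
    units: Sequence[tuple[Mapping[str, float], float]],
    table: GroupContributionTable,
    mode: CopolymerMode = "parameter_average",
) -> SolubilityParameters:
    """Solubility parameters of a copolymer from its repeat units.

    ``units`` is a sequence of ``(group_counts, mole_fraction)`` pairs, all
    under the same method (the shared ``table``); fractions must sum to 1.

    Two averaging conventions are offered:

    * ``parameter_average`` (default): each unit's parameters are computed
      separately and the mole-fraction-weighted mean of each *parameter*
      (components, total, and molar volume alike) is returned.  This is the
      convention that reproduces published copolymer values computed
      unit-by-unit; the averaged total is close to, but not exactly, the
      quadrature of the averaged components.
    * ``repeat_unit_average``: the group counts themselves are averaged into
      one hypothetical mean repeat unit and the single-unit formula applied
      to it.  Equivalent for the molar volume and for Fedors energies close
      in density, but not in general, because delta is not linear in counts.
    """
    if not units:
        raise ValidationError("at least one repeat unit is required")
    fractions = [f for _, f in units]
    if any(f < 0 for f in fractions):
        raise ValidationError("mole fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"mole fractions sum to {sum(fractions)}, expected 1")
    if mode == "repeat_unit_average":
        averaged: dict[str, float] = {}
        for counts, frac in units:
            for label, n in counts.items():
                averaged[label] = averaged.get(label, 0.0) + frac * n
        return single_unit_parameters(averaged, table)
    if mode != "parameter_average":
        raise ConfigurationError(f"unknown copolymer mode {mode!r}")

    per_unit = [single_unit_parameters(counts, table) for counts, _ in units]
    volume = sum(f * p.molar_volume for p, (_, f) in zip(per_unit, units))
    total = sum(f * p.delta_total for p, (_, f) in zip(per_unit, units))
    if table.method_id == "fedors":
        return SolubilityParameters("fedors", total, volume)
    d = sum(f * p.delta_d for p, (_, f) in zip(per_unit, units))  # type: ignore[operator]
    p_ = sum(f * p.delta_p for p, (_, f) in zip(per_unit, units))  # type: ignore[operator]
    h = sum(f * p.delta_h for p, (_, f) in zip(per_unit, units))  # type: ignore[operator]
    return SolubilityParameters(
        "van_krevelen",
        total,
        volume,
        delta_d=d,
        delta_p=p_,
        delta_h=h,
        averaged=True,
    )


def compound_parameters(
    compound: CompoundDescriptor,
    table: GroupContributionTable,
    mode: CopolymerMode = "parameter_average",
) -> SolubilityParameters:
    """Parameters of a compound, routing copolymers through the unit average."""
    if compound.repeat_units:
        units = []
        for unit in compound.repeat_units:
            if table.method_id not in unit.group_counts:
                raise ConfigurationError(
                    f"{compound.abbreviation}/{unit.name}: no counts for {table.method_id}"
                )
            units.append((unit.group_counts[table.method_id], unit.fraction))
        return copolymer_parameters(units, table, mode=mode)
    return single_unit_parameters(compound.counts_for(table.method_id), table)


def polymer_chain_volume(mw: float, density: float) -> float:
    """Molar volume of a whole polymer chain, Mw / rho (cm^3/mol).

    This is the volume that enters the Flory-Huggins lattice ratio; it is
    distinct from (and typically orders of magnitude larger than) the
    group-contribution molar volume of the repeat unit.
    """
    if mw <= 0 or density <= 0:
        raise DomainError("Mw and density must be positive")
    return mw / density


# ---------------------------------------------------------------------------
# fixture loading


def load_group_table(path) -> GroupContributionTable:
    """Read a group-contribution table from tab-separated text.

    Format: optional ``#`` comment lines, a ``method<TAB><id>`` line, a
    header row, then one row per group.  Fedors columns are
    ``label  E  V``; van Krevelen columns are ``label  Fd  Fp  Eh  V``.
    """
    method = None
    header_seen = False
    entries: dict[str, FedorsEntry | VanKrevelenEntry] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if method is None:
                if fields[0] != "method" or len(fields) != 2:
                    raise ValidationError(f"{path}: expected a 'method' line, got {line!r}")
                method = fields[1]
                continue
            if not header_seen:
                header_seen = True
                continue
            label = fields[0]
            if label in entries:
                raise ValidationError(f"{path}: duplicate group label {label!r}")
            if method == "fedors":
                if len(fields) != 3:
                    raise ValidationError(f"{path}: Fedors rows need 3 columns: {line!r}")
                entries[label] = FedorsEntry(float(fields[1]), float(fields[2]))
            else:
                if len(fields) != 5:
                    raise ValidationError(f"{path}: van Krevelen rows need 5 columns: {line!r}")
                entries[label] = VanKrevelenEntry(
                    float(fields[1]), float(fields[2]), float(fields[3]), float(fields[4])
                )
    if method is None:
        raise ValidationError(f"{path}: empty table")
    return GroupContributionTable(method_id=method, entries=entries)


def load_compound(path) -> CompoundDescriptor:
    """Read a compound descriptor from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    units = None
    if "repeat_units" in raw:
        units = tuple(
            RepeatUnit(u["name"], float(u["fraction"]), u["group_counts"])
            for u in raw["repeat_units"]
        )
    return CompoundDescriptor(
        name=raw["name"],
        abbreviation=raw["abbreviation"],
        role=raw["role"],
        mw=float(raw["mw"]),
        tg_c=float(raw["tg_c"]),
        group_counts=raw.get("group_counts", {}),
        tm_c=float(raw["tm_c"]) if raw.get("tm_c") is not None else None,
        true_density=(
            float(raw["true_density"]) if raw.get("true_density") is not None else None
        ),
        gfa_class=raw.get("gfa_class"),
        repeat_units=units,
        notes=raw.get("notes"),
    )
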