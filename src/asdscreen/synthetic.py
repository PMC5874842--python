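"""Synthetic calorimetry, diffraction and screening-campaign generators.

Every stage of the screening pipeline can be exercised without instrument
data: modulated-DSC-like traces (reversing heat flow carrying glass
transition steps, total heat flow adding melting/recrystallization/
mesophase peaks), powder-diffraction-like patterns (amorphous halo plus
optional sharp Bragg peaks), and whole screening campaigns in which the
true maximum miscible drug loading of every drug-polymer pair and the bias
of every preparation method are planted and therefore known exactly.

All generators are deterministic for a fixed seed.  The mixed glass
transition of a one-phase dispersion is placed by the Fox rule

    1/Tg_mix = w_drug/Tg_drug + (1 - w_drug)/Tg_polymer   (temperatures in K)

which is used purely as a plausible monotone interpolant between the pure
values, not as a physical claim about the simulated systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import norm

from .classify import METHOD_IDS, ClassLabel, ObservationRecord, TgEvent
from .constants import DOMAIN_DETECTION_LIMIT_NM, c_to_k, k_to_c
from .errors import ValidationError
from .groups import CompoundDescriptor

EventKind = Literal["glass_transition", "melting", "recrystallization", "mesophase"]

#: Logistic steps: the 1%-99% transition span equals ``2 * ln(99) * scale``.
_LOGISTIC_SPAN = 2.0 * math.log(99.0)


@dataclass(frozen=True)
class ThermalEventSpec:
    """One planted thermal event.

    ``magnitude`` is the heat-capacity step height for a glass transition
    and the peak area for melting/recrystallization/mesophase events; on
    the total-heat-flow sign convention endotherms are negative and
    exotherms positive.
    """

    kind: EventKind
    center_c: float
    width_c: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.width_c <= 0:
            raise ValidationError("event width must be positive")
        if self.magnitude == 0:
            raise ValidationError("event magnitude must be nonzero")
        if self.kind == "melting" and self.magnitude > 0:
            raise ValidationError("melting endotherms are negative on total heat flow")
        if self.kind == "recrystallization" and self.magnitude < 0:
            raise ValidationError("recrystallization exotherms are positive")


@dataclass(frozen=True)
class SyntheticTrace:
    """A generated thermogram with its ground truth."""

    temperature_c: np.ndarray
    reverse_heat_flow: np.ndarray
    total_heat_flow: np.ndarray
    ground_truth: tuple[ThermalEventSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        n = len(self.temperature_c)
        if len(self.reverse_heat_flow) != n or len(self.total_heat_flow) != n:
            raise ValidationError("trace arrays must have equal length")


def default_grid(t_min: float = -90.0, t_max: float = 300.0, step: float = 0.1) -> np.ndarray:
    """Uniform temperature grid, degC."""
    return np.arange(t_min, t_max + step / 2, step)


def make_thermogram(
    events: Sequence[ThermalEventSpec],
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticTrace:
    """Synthesize reversing and total heat-flow signals.

    The reversing signal is a sum of logistic steps (one per glass
    transition; the analytic inflection point of each step sits at its
    specified center, and the 1%-99% span of the step equals the specified
    onset-to-end width).  The total signal adds Gaussian peaks for melting,
    recrystallization and mesophase events, plus i.i.d. Gaussian noise on
    both signals.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    for ev in events:
        if not lo <= ev.center_c <= hi:
            raise ValidationError(
                f"event at {ev.center_c} degC outside grid [{lo}, {hi}]"
            )
    rng = np.random.default_rng(seed)
    reverse = np.zeros_like(grid)
    peaks = np.zeros_like(grid)
    for ev in events:
        if ev.kind == "glass_transition":
            scale = ev.width_c / _LOGISTIC_SPAN
            reverse += ev.magnitude / (1.0 + np.exp(-(grid - ev.center_c) / scale))
        else:
            sigma = ev.width_c / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM -> sigma
            peaks += (
                ev.magnitude
                / (sigma * math.sqrt(2.0 * math.pi))
                * np.exp(-0.5 * ((grid - ev.center_c) / sigma) ** 2)
            )
    if noise_sd > 0:
        reverse = reverse + rng.normal(0.0, noise_sd, grid.shape)
        peaks = peaks + rng.normal(0.0, noise_sd, grid.shape)
    return SyntheticTrace(
        temperature_c=grid,
        reverse_heat_flow=reverse,
        total_heat_flow=reverse + peaks,
        ground_truth=tuple(events),
        seed=seed,
    )


@dataclass(frozen=True)
class ExtractedStep:
    """A glass-transition step recovered from a reversing signal."""

    center_c: float
    width_c: float
    height: float


def extract_tg_steps(
    trace: SyntheticTrace,
    min_height: float = 0.01,
    width_threshold: float = 0.04,
) -> tuple[ExtractedStep, ...]:
    """Locate glass-transition steps in the reversing signal.

    The derivative of a logistic step peaks at the inflection point and
    falls to ~4% of its maximum at the 1%/99% bounds of the step, so the
    span where the derivative exceeds ``width_threshold`` of the local
    peak estimates the onset-to-end width.
    """
    t = trace.temperature_c
    step = t[1] - t[0]
    y = trace.reverse_heat_flow
    window = min(len(y) // 2 * 2 - 1, max(5, int(2.0 / step) // 2 * 2 + 1))
    y = savgol_filter(y, window_length=window, polyorder=3)
    dy = np.gradient(y, t)
    # a logistic step of height h and width w peaks at h*ln(99)/(2w) in the
    # derivative; treat min_height as a floor on detectable step heights,
    # assuming widths up to ~20 degC
    prominence = min_height * _LOGISTIC_SPAN / (4.0 * 20.0)
    idx, _ = find_peaks(dy, prominence=max(prominence, 1e-9), distance=max(1, int(2 / step)))
    out = []
    for i in idx:
        peak = dy[i]
        j_lo = i
        while j_lo > 0 and dy[j_lo - 1] > width_threshold * peak:
            j_lo -= 1
        j_hi = i
        while j_hi < len(dy) - 1 and dy[j_hi + 1] > width_threshold * peak:
            j_hi += 1
        width = t[j_hi] - t[j_lo]
        height = float(np.trapezoid(np.clip(dy[j_lo : j_hi + 1], 0, None), t[j_lo : j_hi + 1]))
        out.append(ExtractedStep(center_c=float(t[i]), width_c=float(width), height=height))
    return tuple(out)


@dataclass(frozen=True)
class ExtractedPeak:
    """A peak recovered from the non-reversing part of the total signal."""

    center_c: float
    area: float  # signed: negative endotherm, positive exotherm


def extract_peaks(trace: SyntheticTrace, min_area: float = 0.05) -> tuple[ExtractedPeak, ...]:
    """Locate melting/recrystallization/mesophase peaks.

    Works on total minus reversing heat flow; the signed area of each peak
    is integrated over its local support.
    """
    t = trace.temperature_c
    resid = trace.total_heat_flow - trace.reverse_heat_flow
    out: list[ExtractedPeak] = []
    for sign in (+1.0, -1.0):
        y = sign * resid
        idx, props = find_peaks(y, prominence=max(min_area, 1e-6))
        for i, left, right in zip(
            idx, props["left_bases"], props["right_bases"]
        ):
            area = sign * float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
            if abs(area) >= min_area:
                out.append(ExtractedPeak(center_c=float(t[i]), area=area))
    return tuple(sorted(out, key=lambda p: p.center_c))


# ---------------------------------------------------------------------------
# powder diffraction


@dataclass(frozen=True)
class XrpdPattern:
    """A synthetic diffractogram over the scanned 2-theta range."""

    two_theta: np.ndarray
    intensity: np.ndarray
    ground_truth_peaks: tuple[tuple[float, float], ...]
    seed: int


def make_xrpd(
    halo_weight: float = 1.0,
    bragg_peaks: Sequence[tuple[float, float]] = (),
    fwhm: float = 0.1,
    noise_sd: float = 0.01,
    seed: int = 0,
    two_theta_min: float = 4.5,
    two_theta_max: float = 30.0,
    step: float = 0.02,
) -> XrpdPattern:
    """Amorphous halo plus optional sharp Bragg peaks plus noise.

    The halo is a broad Gaussian centered mid-range; each Bragg peak is a
    narrow Gaussian of the given full width at half maximum.
    """
    if halo_weight < 0 or any(i < 0 for _, i in bragg_peaks):
        raise ValidationError("halo weight and peak intensities must be non-negative")
    grid = np.arange(two_theta_min, two_theta_max + step / 2, step)
    for pos, _ in bragg_peaks:
        if not two_theta_min <= pos <= two_theta_max:
            raise ValidationError(f"Bragg peak at {pos} deg outside scanned range")
    rng = np.random.default_rng(seed)
    halo_center = 0.5 * (two_theta_min + two_theta_max) * 0.85  # low-angle-weighted hump
    pattern = halo_weight * np.exp(-0.5 * ((grid - halo_center) / 4.0) ** 2)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for pos, intensity in bragg_peaks:
        pattern += intensity * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
    if noise_sd > 0:
        pattern = pattern + rng.normal(0.0, noise_sd, grid.shape)
    return XrpdPattern(
        two_theta=grid,
        intensity=pattern,
        ground_truth_peaks=tuple(bragg_peaks),
        seed=seed,
    )


def detect_crystallinity(
    pattern: XrpdPattern,
    limit_of_detection: float = 0.05,
    max_fwhm: float = 0.5,
) -> bool:
    """Flag a pattern as crystalline if any sharp peak clears the limit.

    A peak counts when its prominence over the local background exceeds
    ``limit_of_detection`` and its width at half prominence is below
    ``max_fwhm`` degrees (the halo itself is far broader).
    """
    step = pattern.two_theta[1] - pattern.two_theta[0]
    idx, props = find_peaks(
        pattern.intensity,
        prominence=limit_of_detection,
        width=(None, max_fwhm / step),
        rel_height=0.5,
    )
    return len(idx) > 0


# ---------------------------------------------------------------------------
# screening campaigns


@dataclass(frozen=True)
class CampaignSpec:
    """Design of a synthetic screening campaign with planted ground truth.

    ``true_boundary`` gives, per (drug, polymer) abbreviation pair, the
    highest drug loading (mass fraction) at which the reference process
    yields a one-phase glass solution.  ``method_bias`` shifts that
    boundary additively per preparation method (positive = the method
    over-predicts miscibility, as quench cooling does; negative = it
    under-predicts, as slow film casting does).  Loadings up to
    ``aa_band`` above the shifted boundary phase-separate while staying
    amorphous (class AA); anything beyond shows residual crystallinity
    (class AC).  ``subresolution_fraction`` of AA samples are assigned
    amorphous domains below the instrument detection limit and therefore
    present a single averaged glass transition: ground truth the
    classifier cannot access.
    """

    drugs: tuple[str, ...]
    polymers: tuple[str, ...]
    loadings: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    methods: tuple[str, ...] = METHOD_IDS
    reference_method: str = "SD"
    true_boundary: Mapping[tuple[str, str], float] = field(default_factory=dict)
    method_bias: Mapping[str, float] = field(default_factory=dict)
    aa_band: float = 0.2
    tg_noise_sd: float = 1.0
    tg_width_c: float = 12.0
    replicates: int = 3
    subresolution_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aa_band < 0:
            raise ValidationError("the amorphous-phase-separation band must be >= 0")
        if not 0.0 <= self.subresolution_fraction <= 1.0:
            raise ValidationError("subresolution fraction must be in [0, 1]")
        for method in self.methods:
            if method not in METHOD_IDS:
                raise ValidationError(f"unknown method {method!r}")
        for (d, p), b in self.true_boundary.items():
            if not 0.0 <= b <= 1.0:
                raise ValidationError(f"boundary for {d}/{p} outside [0, 1]")
            for m in self.methods:
                shifted = b + self.method_bias.get(m, 0.0)
                if not 0.0 <= shifted <= 1.0:
                    raise ValidationError(
                        f"shifted boundary for {d}/{p} under {m} outside [0, 1]"
                    )


def fox_tg(tg_drug_c: float, tg_polymer_c: float, w_drug: float) -> float:
    """Fox-rule mixed glass transition (degC) at drug mass fraction w."""
    if not 0.0 <= w_drug <= 1.0:
        raise ValidationError("drug mass fraction must be in [0, 1]")
    inv = w_drug / c_to_k(tg_drug_c) + (1.0 - w_drug) / c_to_k(tg_polymer_c)
    return k_to_c(1.0 / inv)


def planted_class(
    loading: float, boundary: float, bias: float, aa_band: float
) -> ClassLabel:
    """Class implied by the planted boundary for one condition."""
    shifted = boundary + bias
    if loading <= shifted + 1e-12:
        return "A"
    if loading <= shifted + aa_band + 1e-12:
        return "AA"
    return "AC"


@dataclass(frozen=True)
class CampaignResult:
    """Observation records plus the planted truth they were generated from."""

    records: tuple[ObservationRecord, ...]
    truth: Mapping[tuple[str, str, float, str], ClassLabel]
    spec: CampaignSpec


def make_campaign(
    spec: CampaignSpec,
    compounds: Mapping[str, CompoundDescriptor],
) -> CampaignResult:
    """Generate observation records for a full screening campaign.

    For each (drug, polymer, loading, method, replicate) the planted class
    determines the emitted features: a single Fox-rule mixed glass
    transition for A; a drug-like transition plus a polymer-like transition
    for AA (collapsed to one averaged transition for sub-resolution
    domains); melting (and recrystallization for loadings deep in the
    crystalline regime) plus sharp diffraction for AC.  Gaussian noise of
    sd ``tg_noise_sd`` perturbs every transition temperature.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ObservationRecord] = []
    truth: dict[tuple[str, str, float, str], ClassLabel] = {}
    for drug in spec.drugs:
        for polymer in spec.polymers:
            try:
                boundary = spec.true_boundary[(drug, polymer)]
            except KeyError:
                raise ValidationError(f"no planted boundary for pair {drug}/{polymer}")
            tg_d = compounds[drug].tg_c
            tg_p = compounds[polymer].tg_c
            for loading in spec.loadings:
                for method in spec.methods:
                    label = planted_class(
                        loading, boundary, spec.method_bias.get(method, 0.0), spec.aa_band
                    )
                    truth[(drug, polymer, loading, method)] = label
                    for rep in range(1, spec.replicates + 1):
                        records.append(
                            _emit_record(
                                drug, polymer, loading, method, rep, label,
                                tg_d, tg_p, spec, rng,
                            )
                        )
    return CampaignResult(records=tuple(records), truth=truth, spec=spec)


def _emit_record(
    drug: str,
    polymer: str,
    loading: float,
    method: str,
    replicate: int,
    label: ClassLabel,
    tg_drug: float,
    tg_polymer: float,
    spec: CampaignSpec,
    rng: np.random.Generator,
) -> ObservationRecord:
    noise = lambda: rng.normal(0.0, spec.tg_noise_sd) if spec.tg_noise_sd > 0 else 0.0
    width = spec.tg_width_c
    if label == "A":
        tg = fox_tg(tg_drug, tg_polymer, loading) + noise()
        events = (TgEvent(value=tg, width=width),)
        return ObservationRecord(
            drug=drug, polymer=polymer, drug_loading=loading, method=method,
            tg_events=events, replicate=replicate,
        )
    if label == "AA":
        drug_like = tg_drug + noise()
        polymer_like = tg_polymer + noise()
        # domain-size draw: a lognormal whose median is placed so that the
        # probability of falling below the 30 nm detection limit equals
        # subresolution_fraction (0 disables sub-resolution domains)
        sigma = 0.8
        if spec.subresolution_fraction > 0:
            median = DOMAIN_DETECTION_LIMIT_NM * math.exp(
                -sigma * norm.ppf(spec.subresolution_fraction)
            )
        else:
            median = 120.0
        domain_nm = float(median * math.exp(sigma * rng.standard_normal()))
        if spec.subresolution_fraction > 0 and domain_nm < DOMAIN_DETECTION_LIMIT_NM:
            averaged = 0.5 * (drug_like + polymer_like)
            events = (TgEvent(value=averaged, width=width * 1.5),)
        else:
            events = tuple(
                TgEvent(value=v, width=width)
                for v in sorted((drug_like, polymer_like))
            )
        return ObservationRecord(
            drug=drug, polymer=polymer, drug_loading=loading, method=method,
            tg_events=events, replicate=replicate,
        )
    # AC: residual crystallinity; deep in the crystalline regime the sample
    # also recrystallizes on heating
    recryst = loading > spec.true_boundary[(drug, polymer)] + spec.aa_band + 0.2
    events = (TgEvent(value=tg_drug + noise(), width=width),)
    return ObservationRecord(
        drug=drug, polymer=polymer, drug_loading=loading, method=method,
        tg_events=events, melting_detected=True,
        recrystallization_detected=bool(recryst), xrpd_crystalline=True,
        replicate=replicate,
    )


def planted_max_a_loading(
    spec: CampaignSpec, drug: str, polymer: str, method: str
) -> float | None:
    """Highest loading on the campaign grid whose planted class is A."""
    bias = spec.method_bias.get(method, 0.0)
    boundary = spec.true_boundary[(drug, polymer)]
    eligible = [
        dl for dl in spec.loadings if planted_class(dl, boundary, bias, spec.aa_band) == "A"
    ]
    return max(eligible) if eligible else None
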