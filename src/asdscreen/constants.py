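"""Physical constants and screening defaults.

Unit conventions used throughout the package:

* solubility parameters in MPa^1/2,
* molar volumes in cm^3/mol,
* cohesive energies in J/mol,
* temperatures in degrees Celsius at the API surface, Kelvin internally
  where thermodynamics requires it.

1 cm^3 * MPa = 1 J, so ``v * delta_delta**2`` is directly in J/mol when v is
in cm^3/mol and the solubility-parameter difference in MPa^1/2.
"""

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Ambient reference temperature for screening calculations, K (25 degC).
T_AMBIENT_K = 298.15

#: Empirical entropic offset of the solubility-parameter estimate of the
#: Flory-Huggins interaction parameter (dimensionless).
CHI_EMPIRICAL_OFFSET = 0.34

#: Greenhalgh criterion: |delta_drug - delta_polymer| below this value
#: (MPa^1/2) is read as favourable mixing; the comparison is strict.
GREENHALGH_CUTOFF = 7.0

#: Minimum separation (degC) at which modulated DSC resolves two glass
#: transitions; events closer than this merge into a single apparent step.
TG_RESOLUTION_C = 10.0

#: Default tolerance (degC) for deciding that a measured glass transition
#: coincides with a pure-component value.
TG_MATCH_TOL_C = 3.0

#: Smallest amorphous-domain size (nm) that produces a distinct glass
#: transition in modulated DSC.
DOMAIN_DETECTION_LIMIT_NM = 30.0

ZERO_C_IN_K = 273.15


def c_to_k(t_c: float) -> float:
    """Celsius to Kelvin."""
    return t_c + ZERO_C_IN_K


def k_to_c(t_k: float) -> float:
    """Kelvin to Celsius."""
    return t_k - ZERO_C_IN_K
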