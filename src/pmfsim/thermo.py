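"""Closed-form thermodynamics of the proton motive force (pmf).

The pmf is the sum of an electric term (delta_psi, volts, lumen-positive)
and a concentration term (delta_ph, stroma-minus-lumen pH units) expressed
in volts through ``z = ln(10)·R·T/F`` (~0.0592 V per pH unit at 298.15 K):

    pmf = delta_psi + z * delta_ph

The ATP synthase couples pmf to ATP synthesis through its c-ring: one
proton per c-subunit per rotation, three ATP per rotation, so the H+/ATP
ratio equals ``c_subunits / 3``.  Net synthase flux vanishes at

    pmf_eq = delta_g_atp / (h_per_atp * F)

which is the dark-equilibrium pmf used to initialise every simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: CODATA values, J/(mol K) and C/mol.
GAS_CONSTANT = 8.314
FARADAY = 96485.0

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "CRingConfig",
    "ThermoParams",
    "PmfState",
    "h_plus_per_atp",
    "equilibrium_pmf",
    "partition_pmf",
    "lumen_ph",
    "atp_per_two_nadph",
]


def h_plus_per_atp(c_subunits: int) -> float:
    """Protons required per ATP for a c-ring with ``c_subunits`` subunits.

    One full 360-degree rotation of the rotor translocates one proton per
    c-subunit and turns over the three catalytic sites once, so the ratio
    is ``c_subunits / 3`` (e.g. 14 -> 4.67 for the chloroplast enzyme).
    """
    if isinstance(c_subunits, bool) or not isinstance(c_subunits, (int,)):
        # Accept exact integral floats for convenience, nothing else.
        if isinstance(c_subunits, float) and c_subunits.is_integer():
            c_subunits = int(c_subunits)
        else:
            raise InvalidParameterError(
                f"c_subunits must be a positive integer, got {c_subunits!r}")
    if c_subunits < 1:
        raise InvalidParameterError(
            f"c_subunits must be >= 1, got {c_subunits}")
    return c_subunits / 3.0


@dataclass(frozen=True)
class CRingConfig:
    """ATP synthase c-ring stoichiometry — the experiment's varied factor.

    ``h_per_atp`` is derived (``c_subunits / 3``) and held constant for the
    lifetime of a simulation: the stoichiometry does not vary with
    physiological state.
    """

    c_subunits: int

    def __post_init__(self):
        h_plus_per_atp(self.c_subunits)  # validates

    @property
    def h_per_atp(self) -> float:
        return h_plus_per_atp(self.c_subunits)


@dataclass(frozen=True)
class ThermoParams:
    """Fixed thermodynamic parameters.

    The stroma is treated as infinitely buffered (``stromal_ph`` constant)
    and ``delta_g_atp`` is held fixed — no ADP/Pi mass action.
    """

    delta_g_atp: float = 40_000.0   # J/mol
    stromal_ph: float = 7.8
    temperature: float = 298.15     # K
    faraday: float = FARADAY        # C/mol
    gas_constant: float = GAS_CONSTANT  # J/(mol K)

    def __post_init__(self):
        if self.delta_g_atp < 0:
            raise InvalidParameterError(
                f"delta_g_atp must be >= 0, got {self.delta_g_atp}")
        if self.temperature <= 0:
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature}")

    @property
    def z(self) -> float:
        """Volts per pH unit: ln(10)·R·T/F (~0.0592 V at 298.15 K)."""
        return math.log(10.0) * self.gas_constant * self.temperature / self.faraday


@dataclass(frozen=True)
class PmfState:
    """A pmf decomposed into its electric and concentration components."""

    delta_psi: float   # V, lumen-positive
    delta_ph: float    # pH units, stroma minus lumen
    pmf_total: float   # V
    z: float = field(default=0.05916, repr=False)  # V per pH unit used to compose

    def __post_init__(self):
        residual = self.pmf_total - (self.delta_psi + self.z * self.delta_ph)
        if abs(residual) > 1e-12:
            raise InvalidParameterError(
                f"pmf_total must equal delta_psi + z*delta_ph "
                f"(residual {residual:.3e} V)")

    def delta_mu_h(self, thermo: ThermoParams) -> float:
        """Per-proton electrochemical potential, J/mol (= F * pmf_total)."""
        return thermo.faraday * self.pmf_total


def equilibrium_pmf(thermo: ThermoParams, ring: CRingConfig) -> float:
    """pmf (V) at which net ATP synthase flux is zero.

    From ``delta_g_atp = h_per_atp * F * pmf``: 40 kJ/mol gives ~89 mV for
    c14 and ~155 mV for c8.
    """
    n = ring.h_per_atp
    if n == 0:
        raise InvalidParameterError("h_per_atp must be non-zero")
    if thermo.delta_g_atp < 0:
        raise InvalidParameterError("delta_g_atp must be >= 0")
    return thermo.delta_g_atp / (n * thermo.faraday)


def partition_pmf(pmf_total: float, fraction_psi: float,
                  thermo: ThermoParams) -> PmfState:
    """Split a total pmf into delta_psi and delta_ph components.

    ``fraction_psi`` is the fraction stored in the electric field; the
    remainder is carried by the pH gradient (converted through ``z``).
    """
    if not math.isfinite(pmf_total):
        raise InvalidParameterError(f"pmf_total must be finite, got {pmf_total}")
    if not 0.0 <= fraction_psi <= 1.0:
        raise InvalidParameterError(
            f"fraction_psi must lie in [0, 1], got {fraction_psi}")
    delta_psi = fraction_psi * pmf_total
    delta_ph = (1.0 - fraction_psi) * pmf_total / thermo.z
    return PmfState(delta_psi=delta_psi, delta_ph=delta_ph,
                    pmf_total=delta_psi + thermo.z * delta_ph, z=thermo.z)


def lumen_ph(stromal_ph: float, delta_ph: float) -> float:
    """Lumen pH given stromal pH and the trans-membrane pH difference."""
    return stromal_ph - delta_ph


def atp_per_two_nadph(ring: CRingConfig, h_per_electron: float = 3.0) -> float:
    """ATP produced per 2 NADPH by linear electron flow.

    2 NADPH require 4 electrons; each electron deposits ``h_per_electron``
    protons in the lumen (default 3: one from water oxidation plus two from
    the b6f Q-cycle).  For the chloroplast c14 ring this yields
    12 / 4.67 = 2.57 ATP per 2 NADPH — below the 3.0 the CBB cycle needs.
    """
    if h_per_electron < 0:
        raise InvalidParameterError(
            f"h_per_electron must be >= 0, got {h_per_electron}")
    return (4.0 * h_per_electron) / ring.h_per_atp
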