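"""Right-hand side of the light-reaction ODE system.

State and fluxes are expressed per mole of PSII (PSII : PSI : b6f = 1:1:1,
plastoquinone pool 6 per PSII, i.e. 12 electron equivalents).  The membrane
is a capacitor: translocated charge maps to delta_psi through
``c_membrane`` (V per unit charge).  Lumen pH integrates net proton flux
through the buffering capacity ``beta_lumen``.

The processes assembled by :func:`derivatives`:

* PSII excitation (light-driven Q_A reduction, attenuated by qE),
* Q_A- -> plastoquinone pool transfer,
* PQH2 oxidation at b6f, throttled by lumen pH (photosynthetic control),
* PSI turnover to a non-limiting terminal acceptor (completes LEF),
* S2/S3 Q_A- charge recombination, exponential in delta_psi, with a fixed
  singlet-oxygen yield per event,
* ohmic ATP synthase proton efflux around the c-ring equilibrium pmf,
* ohmic counter-ion flux that relaxes delta_psi toward a set point,
  re-partitioning pmf into the pH gradient.

Several rate constants and membrane constants are calibrations, not
measured values; see the field comments on :class:`KineticParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import IntegrationError, InvalidParameterError
from .light import LightProtocol
from .thermo import CRingConfig, ThermoParams, equilibrium_pmf

__all__ = [
    "ModelState",
    "KineticParams",
    "STATE_FIELDS",
    "solve_pka_reg",
    "b6f_rate_constant",
    "psbs_protonation_target",
    "vde_activity",
    "zeaxanthin_steady_state",
    "qe_extent",
    "recombination_rate",
    "singlet_o2_rate",
    "atp_synthase_flux",
    "counter_ion_flux",
    "fluxes",
    "derivatives",
]

#: Order of the ODE state vector.
STATE_FIELDS = (
    "qa_reduced",          # fraction of PSII with Q_A-
    "pq_reduced",          # fraction of PQ-pool electron capacity filled
    "p700_ox",             # fraction P700+
    "lumen_ph",            # lumen pH (state variable; free [H+] derivable)
    "delta_psi",           # V, lumen-positive
    "s23_donor_frac",      # fraction of PSII donor sides in S2/S3
    "psbs_protonated",     # fraction
    "zeaxanthin",          # fraction de-epoxidated
    "cumulative_lef",      # mol e- per mol PSII (integral of PSI flux)
    "cumulative_singlet_o2",  # events per PSII (integral)
    "cumulative_separations",  # PSII charge separations per PSII (integral)
    "cumulative_recombination",  # recombination events per PSII (integral)
    "cumulative_charge",   # net electrogenic charge translocated (integral)
    "counter_ion_moved",   # net counter-ion charge moved (integral)
)


@dataclass
class ModelState:
    """Time-dependent state of the thylakoid model (per mol PSII basis)."""

    qa_reduced: float = 0.0
    pq_reduced: float = 0.05
    p700_ox: float = 0.0
    lumen_ph: float = 7.8
    delta_psi: float = 0.0
    s23_donor_frac: float = 0.0
    psbs_protonated: float = 0.0
    zeaxanthin: float = 0.0
    cumulative_lef: float = 0.0
    cumulative_singlet_o2: float = 0.0
    cumulative_separations: float = 0.0
    cumulative_recombination: float = 0.0
    cumulative_charge: float = 0.0
    counter_ion_moved: float = 0.0

    @property
    def lumen_h(self) -> float:
        """Free lumen proton concentration, mol/L."""
        return 10.0 ** (-self.lumen_ph)

    @property
    def s23_qa_frac(self) -> float:
        """Fraction of PSII that is recombination-competent (S2/S3 with Q_A-).

        Always <= qa_reduced because s23_donor_frac <= 1.
        """
        return self.qa_reduced * self.s23_donor_frac

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, y)})

    def validate(self, eps: float = 1e-9) -> None:
        """Raise if any fraction leaves [-eps, 1+eps] or lumen pH is absurd."""
        for name in ("qa_reduced", "pq_reduced", "p700_ox", "s23_donor_frac",
                     "psbs_protonated", "zeaxanthin"):
            v = getattr(self, name)
            if not (-eps <= v <= 1.0 + eps):
                raise IntegrationError(
                    f"state fraction out of [0, 1]: {name}={v!r}", term=name)
        if not (0.0 < self.lumen_ph < 14.0):
            raise IntegrationError(
                f"lumen_ph out of range: {self.lumen_ph!r}", term="lumen_ph")


def solve_pka_reg(n_hill: float, k_ratio: float = 10.0,
                  ph_hi: float = 7.5, ph_lo: float = 5.5) -> float:
    """pKa of the b6f control sigmoid giving rate(ph_hi)/rate(ph_lo) = k_ratio.

    For ``k = k_max / (1 + 10^(n*(pKa - pH)))`` the constraint has the
    closed-form solution ``pKa = log10(u) / n`` with
    ``u = (k_ratio - 1) / (10^(-n*ph_lo) - k_ratio * 10^(-n*ph_hi))``.
    With n = 1 and the canonical ten-fold span over pH 5.5–7.5 this gives
    exactly 6.5.
    """
    if n_hill <= 0:
        raise InvalidParameterError(f"n_hill must be > 0, got {n_hill}")
    a = 10.0 ** (-n_hill * ph_lo)
    b = 10.0 ** (-n_hill * ph_hi)
    denom = a - k_ratio * b
    if denom <= 0:
        raise InvalidParameterError(
            f"no pKa achieves a {k_ratio}-fold span with n_hill={n_hill}")
    u = (k_ratio - 1.0) / denom
    return math.log10(u) / n_hill


@dataclass(frozen=True)
class KineticParams:
    """Rate constants, conductances and membrane constants.

    The source model publishes no numeric values for k_r, the stabilisation
    energy, f_dist, g_atpase, c_membrane or beta_lumen — every default
    below marked CALIBRATED was chosen to land the model in literature-
    typical regimes (a single saturating flash gives ~0.05 V; ten minutes
    of 1000 umol photons m-2 s-1 with a c14 ring drives lumen pH into the
    5.8–6.3 range) and must not be read as measured quantities.
    """

    # --- excitation & electron transfer -----------------------------------
    #: PSII/PSI excitation rate per unit light, s-1 per (umol photons m-2 s-1).
    antenna_rate_per_intensity: float = 0.2
    #: maximal quenching of PSII excitation at full qE.
    qe_max: float = 0.5
    #: Q_A- -> PQ pool electron transfer rate constant, s-1. CALIBRATED.
    k_qa_pq: float = 500.0
    #: electron capacity of the PQ pool per PSII (6 PQ x 2 e-).
    pq_pool_e_capacity: float = 12.0
    #: maximal PQH2 oxidation rate constant at b6f, s-1 (the rate-limiting
    #: step of linear electron flow). CALIBRATED.
    k_b6f_max: float = 80.0
    #: Hill cooperativity of photosynthetic control.
    n_hill_b6f: float = 1.0
    #: pH midpoint of photosynthetic control; None -> solved so that
    #: rate(7.5)/rate(5.5) is exactly ten-fold.
    pka_reg: Optional[float] = None

    # --- recombination / singlet oxygen -----------------------------------
    #: intrinsic S2/S3 Q_A- recombination rate at delta_psi = 0, s-1, with
    #: the charge-separated-state stabilisation energy folded in. CALIBRATED.
    k_r: float = 0.15
    #: stabilisation free energy offset, eV.  Kept for interface
    #: completeness; folded into k_r by default (0.0).
    delta_e_stab: float = 0.0
    #: dielectric-weighted fraction of delta_psi felt by the recombining pair.
    f_dist: float = 1.0
    #: volts of delta_psi per decade of recombination rate.
    psi_per_decade: float = 0.06
    #: singlet-oxygen yield per recombination event.
    phi_1o2: float = 0.25

    # --- proton circuit ----------------------------------------------------
    #: ATP synthase proton conductance, H+ s-1 V-1 per PSII (held constant
    #: at the maximal activity regime; activation always "on"). CALIBRATED.
    g_atpase: float = 800.0
    #: V per unit translocated charge per PSII (one charge/PSII ~ 0.05 V).
    #: CALIBRATED.
    c_membrane: float = 0.05
    #: lumen buffering capacity, H+ per pH unit per PSII. CALIBRATED.
    beta_lumen: float = 20.0
    #: counter-ion channel conductance, charge s-1 V-1 per PSII. CALIBRATED.
    g_ion: float = 20.0
    #: delta_psi toward which counter-ions relax (the generic monovalent
    #: ion's Nernst equilibrium); None -> set to the dark-equilibrium
    #: delta_psi during equilibration.
    delta_psi_ion_eq: Optional[float] = None
    #: protons deposited per electron at the OEC / at b6f (sum = 3 with the
    #: Q-cycle engaged).
    h_oec_per_e: float = 1.0
    h_b6f_per_e: float = 2.0

    # --- qE ----------------------------------------------------------------
    pka_psbs: float = 6.5
    n_psbs: float = 2.0
    #: PsbS protonation relaxation rate, s-1 (fast).
    k_psbs: float = 5.0
    pka_vde: float = 6.0
    n_vde: float = 2.0
    #: zeaxanthin formation (VDE) / reversal (epoxidase) rates, s-1 (slow).
    k_vde: float = 0.1
    k_ep: float = 0.004

    # --- housekeeping ------------------------------------------------------
    #: dark relaxation of S2/S3 donor states, s-1.
    k_s_decay: float = 0.03
    #: dark poise of the PQ pool (fraction reduced).
    pq_reduced_dark: float = 0.05

    def __post_init__(self):
        for name in ("antenna_rate_per_intensity", "k_qa_pq", "k_b6f_max",
                     "k_r", "g_atpase", "g_ion", "k_psbs", "k_vde", "k_ep",
                     "k_s_decay", "beta_lumen", "c_membrane",
                     "pq_pool_e_capacity"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("phi_1o2", "f_dist", "qe_max", "pq_reduced_dark"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("pka_psbs", "pka_vde"):
            v = getattr(self, name)
            if not 4.0 <= v <= 8.0:
                raise InvalidParameterError(f"{name} must lie in [4, 8], got {v}")
        if self.pka_reg is not None and not 4.0 <= self.pka_reg <= 8.0:
            raise InvalidParameterError(
                f"pka_reg must lie in [4, 8], got {self.pka_reg}")
        if self.psi_per_decade <= 0:
            raise InvalidParameterError("psi_per_decade must be > 0")

    def resolved(self, ring: CRingConfig, thermo: ThermoParams,
                 fraction_psi: float = 0.5) -> "KineticParams":
        """Return a copy with derived fields filled in.

        ``pka_reg`` is solved for the ten-fold control span when unset, and
        ``delta_psi_ion_eq`` defaults to the dark-equilibrium delta_psi of
        the given ring/partition so that the counter-ion system is at rest
        in the dark.
        """
        pka = self.pka_reg
        if pka is None:
            pka = solve_pka_reg(self.n_hill_b6f)
        psi_eq = self.delta_psi_ion_eq
        if psi_eq is None:
            psi_eq = fraction_psi * equilibrium_pmf(thermo, ring)
        return replace(self, pka_reg=pka, delta_psi_ion_eq=psi_eq)


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def b6f_rate_constant(lumen_ph_value: float, params: KineticParams) -> float:
    """PQH2 oxidation rate constant at b6f as a function of lumen pH, s-1.

    Hill sigmoid, increasing in pH, saturating at ``k_b6f_max``; with the
    solved midpoint the rate falls ten-fold from pH 7.5 to pH 5.5
    (photosynthetic control).
    """
    pka = params.pka_reg if params.pka_reg is not None \
        else solve_pka_reg(params.n_hill_b6f)
    return params.k_b6f_max / (
        1.0 + 10.0 ** (params.n_hill_b6f * (pka - lumen_ph_value)))


def _hill_protonation(ph: float, pka: float, n: float) -> float:
    """Fraction protonated for a site of given pKa (increases as pH falls)."""
    return 1.0 / (1.0 + 10.0 ** (n * (ph - pka)))


def psbs_protonation_target(lumen_ph_value: float, params: KineticParams) -> float:
    """Steady-state PsbS protonation at a given lumen pH."""
    return _hill_protonation(lumen_ph_value, params.pka_psbs, params.n_psbs)


def vde_activity(lumen_ph_value: float, params: KineticParams) -> float:
    """Relative violaxanthin de-epoxidase activity at a given lumen pH."""
    return _hill_protonation(lumen_ph_value, params.pka_vde, params.n_vde)


def zeaxanthin_steady_state(lumen_ph_value: float, params: KineticParams) -> float:
    """Zeaxanthin fraction balancing VDE formation against epoxidation."""
    v = params.k_vde * vde_activity(lumen_ph_value, params)
    if v + params.k_ep == 0.0:
        return 0.0
    return v / (v + params.k_ep)


def qe_extent(lumen_ph_value: float, state: Optional[ModelState],
              params: KineticParams) -> float:
    """qE quenching extent in [0, 1].

    Product of PsbS protonation (fast) and zeaxanthin fraction (slow).
    With ``state`` given, the dynamic protonation/zeaxanthin values are
    used; with ``state=None`` the steady-state values at ``lumen_ph_value``
    are used (as in the dark-equilibrium tables).
    """
    if state is None:
        psbs = psbs_protonation_target(lumen_ph_value, params)
        zea = zeaxanthin_steady_state(lumen_ph_value, params)
    else:
        psbs = state.psbs_protonated
        zea = state.zeaxanthin
    return psbs * zea


def recombination_rate(state: ModelState, params: KineticParams) -> float:
    """S2/S3 Q_A- recombination rate, events s-1 per PSII.

    Exponential (base-10) in delta_psi: equal to ``s23_qa_frac * k_r`` at
    delta_psi = 0 and tenfold larger for every ``psi_per_decade / f_dist``
    volts.  The stabilisation-energy offset multiplies in as
    ``10^(delta_e_stab / psi_per_decade)`` (0 by default — folded into k_r).
    """
    exponent = (params.delta_e_stab
                + params.f_dist * state.delta_psi) / params.psi_per_decade
    if exponent > 300.0:  # surfaces as a named integration failure upstream
        return math.inf if state.s23_qa_frac > 0 else 0.0
    return state.s23_qa_frac * params.k_r * 10.0 ** exponent


def singlet_o2_rate(state: ModelState, params: KineticParams) -> float:
    """Singlet-oxygen production rate, events s-1 per PSII."""
    return params.phi_1o2 * recombination_rate(state, params)


def atp_synthase_flux(pmf_total: float, ring: CRingConfig,
                      thermo: ThermoParams, params: KineticParams) -> float:
    """Proton efflux through the ATP synthase, H+ s-1 per PSII.

    Ohmic in the displacement from the c-ring's equilibrium pmf; negative
    below equilibrium (ATP hydrolysis direction).  The enzyme is treated as
    permanently activated (thiol-reduced).
    """
    return params.g_atpase * (pmf_total - equilibrium_pmf(thermo, ring))


def counter_ion_flux(state: ModelState, params: KineticParams) -> float:
    """Ohmic counter-ion charge efflux, charge s-1 per PSII.

    Positive flux discharges delta_psi toward ``delta_psi_ion_eq``,
    re-partitioning pmf into the pH gradient; with ``g_ion = 0`` pmf stays
    in delta_psi.
    """
    psi_eq = params.delta_psi_ion_eq if params.delta_psi_ion_eq is not None else 0.0
    return params.g_ion * (state.delta_psi - psi_eq)


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

def fluxes(t: float, state: ModelState, ring: CRingConfig,
           thermo: ThermoParams, params: KineticParams,
           light: LightProtocol) -> dict:
    """All instantaneous fluxes (s-1 per PSII) plus derived observables."""
    intensity = light.intensity(t)
    qe = qe_extent(state.lumen_ph, state, params)
    exc = params.antenna_rate_per_intensity * intensity

    v_psii = exc * (1.0 - params.qe_max * qe) * (1.0 - state.qa_reduced)
    v_qa_pq = params.k_qa_pq * state.qa_reduced * (1.0 - state.pq_reduced)
    k_b6f = b6f_rate_constant(state.lumen_ph, params)
    v_b6f = k_b6f * state.pq_reduced * state.p700_ox
    v_psi = exc * (1.0 - state.p700_ox)
    v_recomb = recombination_rate(state, params)
    v_1o2 = params.phi_1o2 * v_recomb

    delta_ph = thermo.stromal_ph - state.lumen_ph
    pmf_total = state.delta_psi + thermo.z * delta_ph
    v_atp = atp_synthase_flux(pmf_total, ring, thermo, params)
    v_ion = counter_ion_flux(state, params)

    # OEC protons ride on stable turnover (S-state advancement), not on raw
    # separations: a separation that later recombines oxidises no water.
    h_in = params.h_oec_per_e * v_qa_pq + params.h_b6f_per_e * v_b6f
    h_out = v_atp
    # Each electron-transfer step moves one charge across the membrane;
    # recombination reverses the PSII separation.  H+ deposition is the
    # lumen-side half of those same electrogenic steps — not counted twice.
    charge_net = (v_psii - v_recomb) + v_b6f + v_psi - v_atp - v_ion

    return {
        "intensity": intensity,
        "v_psii": v_psii,
        "v_qa_pq": v_qa_pq,
        "v_b6f": v_b6f,
        "v_psi": v_psi,
        "v_recombination": v_recomb,
        "v_singlet_o2": v_1o2,
        "v_atp_synthase": v_atp,
        "v_counter_ion": v_ion,
        "h_in": h_in,
        "h_out": h_out,
        "charge_net": charge_net,
        "pmf_total": pmf_total,
        "delta_ph": delta_ph,
        "b6f_rate_constant": k_b6f,
        "qe_extent": qe,
    }


def derivatives(t: float, state: ModelState, ring: CRingConfig,
                thermo: ThermoParams, params: KineticParams,
                light: LightProtocol) -> np.ndarray:
    """Time derivative of the state vector (order of ``STATE_FIELDS``)."""
    fx = fluxes(t, state, ring, thermo, params, light)
    for name, v in fx.items():
        if not math.isfinite(v):
            raise IntegrationError(
                f"non-finite flux during RHS evaluation at t={t!r}",
                last_time=t, term=name)

    d_qa = fx["v_psii"] - fx["v_qa_pq"] - fx["v_recombination"]
    d_pq = (fx["v_qa_pq"] - fx["v_b6f"]) / params.pq_pool_e_capacity
    d_p700_ox = fx["v_psi"] - fx["v_b6f"]
    d_lumen_ph = -(fx["h_in"] - fx["h_out"]) / params.beta_lumen
    d_delta_psi = params.c_membrane * fx["charge_net"]
    # Stable PSII turnover walks the OEC around its four S-states (time
    # average: half the centers in S2/S3); recombination resets S2/S3 -> S1.
    d_s23 = (2.0 * fx["v_qa_pq"] * (0.5 - state.s23_donor_frac)
             - fx["v_recombination"]
             - params.k_s_decay * state.s23_donor_frac)
    d_psbs = params.k_psbs * (
        psbs_protonation_target(state.lumen_ph, params) - state.psbs_protonated)
    d_zea = (params.k_vde * vde_activity(state.lumen_ph, params)
             * (1.0 - state.zeaxanthin) - params.k_ep * state.zeaxanthin)

    return np.array([
        d_qa,
        d_pq,
        d_p700_ox,
        d_lumen_ph,
        d_delta_psi,
        d_s23,
        d_psbs,
        d_zea,
        fx["v_psi"],            # cumulative_lef
        fx["v_singlet_o2"],     # cumulative_singlet_o2
        fx["v_psii"],           # cumulative_separations
        fx["v_recombination"],  # cumulative_recombination
        fx["charge_net"],       # cumulative_charge
        fx["v_counter_ion"],    # counter_ion_moved
    ])
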