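"""Modified TP06 human ventricular cell model (endocardial variant).

The kinetics are the ten Tusscher--Panfilov 2006 endocardial formulation
with two modifications that reduce repolarization reserve and promote
early afterdepolarizations (EADs):

* the maximal L-type Ca conductance ``G_CaL`` is doubled relative to the
  published endocardial value (baseline here is ``2 x 0.00003980``), and
* the voltage inactivation time constant ``tau_f`` of the L-type channel
  is scaled by ``tau_f_scale`` (default 0.5, i.e. twofold faster).

On top of that baseline, four dimensionless multipliers (``mult_CaL``,
``mult_Ks``, ``mult_Kr``, ``mult_NaCa``) scale the maximal conductances
of I_CaL, I_Ks, I_Kr and the Na/Ca exchanger; sweeping them maps the
normal / EAD / oscillatory phase diagram.

Units follow the TP06 convention: voltage mV, time ms, currents pA/pF,
concentrations mM, T = 310 K.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "CellState",
    "CurrentSet",
    "make_params",
    "compute_currents",
    "step_cell",
    "rhs",
    "find_rest_state",
    "TP06_INITIAL_STATE",
    "STATE_FIELDS",
]

# Ordering of the packed state vector used by the integrators.
STATE_FIELDS = (
    "V",
    "m", "h", "j",
    "d", "f", "f2", "f_cass",
    "r", "s",
    "xr1", "xr2", "xs",
    "na_i", "k_i", "ca_i", "ca_ss", "ca_sr", "r_bar",
)
N_STATE = len(STATE_FIELDS)

GATE_FIELDS = ("m", "h", "j", "d", "f", "f2", "f_cass", "r", "s", "xr1", "xr2", "xs")


@dataclass(frozen=True)
class ModelParams:
    """Full endocardial TP06 constant set plus the EAD scaling knobs.

    ``*_base`` values are the baseline maximal conductances; the
    effective conductances used by the equations are base x multiplier
    (see the ``g_*_eff`` properties).
    """

    # scaling knobs
    mult_CaL: float = 1.0
    mult_Ks: float = 1.0
    mult_Kr: float = 1.0
    mult_NaCa: float = 1.0
    tau_f_scale: float = 0.5

    # baselines of the swept channels; g_CaL_base already includes the
    # factor-2 increase over the published endocardial TP06 value
    g_CaL_base: float = 2.0 * 0.00003980   # mm^3 uF^-1 ms^-1
    g_Ks_base: float = 0.3923027           # nS/pF
    g_Kr_base: float = 0.1532432           # nS/pF
    k_NaCa_base: float = 1000.0            # pA/pF

    # membrane capacitance per unit area in the voltage equation
    # (currents are already per pF, so this is 1 in TP06 units)
    C_m: float = 1.0
    # cell capacitance used in the concentration bookkeeping [uF]
    cap: float = 0.185

    # physical constants
    R: float = 8314.472      # mJ mol^-1 K^-1
    T: float = 310.0         # K
    F: float = 96485.3415    # C/mol

    # external concentrations [mM]
    na_o: float = 140.0
    k_o: float = 5.4
    ca_o: float = 2.0

    # fixed maximal conductances
    g_Na: float = 14.838
    g_K1: float = 5.405
    g_to: float = 0.073      # endocardial
    g_pCa: float = 0.1238
    g_pK: float = 0.0146
    g_bNa: float = 0.00029
    g_bCa: float = 0.000592

    # I_NaK
    p_NaK: float = 2.724
    km_K: float = 1.0
    km_Na: float = 40.0

    # I_NaCa sub-constants
    km_Nai: float = 87.5
    km_Ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35
    alpha_naca: float = 2.5

    # I_pCa
    kp_Ca: float = 0.0005

    # I_Ks Na permeability ratio
    p_KNa: float = 0.03

    # geometry [um^3 scaled as in TP06]
    v_c: float = 0.016404
    v_sr: float = 0.001094
    v_ss: float = 0.00005468

    # buffering
    buf_c: float = 0.2
    k_buf_c: float = 0.001
    buf_sr: float = 10.0
    k_buf_sr: float = 0.3
    buf_ss: float = 0.4
    k_buf_ss: float = 0.00025

    # SR fluxes
    v_maxup: float = 0.006375
    k_up: float = 0.00025
    v_rel: float = 0.102
    v_leak: float = 0.00036
    v_xfer: float = 0.0038

    # ryanodine receptor
    k1_prime: float = 0.15
    k2_prime: float = 0.045
    k3: float = 0.060
    k4: float = 0.005
    ec_sr: float = 1.5
    max_sr: float = 2.5
    min_sr: float = 1.0

    def __post_init__(self):
        for name in ("mult_CaL", "mult_Ks", "mult_Kr", "mult_NaCa"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not math.isfinite(self.tau_f_scale) or self.tau_f_scale <= 0:
            raise ValueError(f"tau_f_scale must be > 0, got {self.tau_f_scale}")

    # effective conductances -------------------------------------------------
    @property
    def g_CaL_eff(self) -> float:
        return self.mult_CaL * self.g_CaL_base

    @property
    def g_Ks_eff(self) -> float:
        return self.mult_Ks * self.g_Ks_base

    @property
    def g_Kr_eff(self) -> float:
        return self.mult_Kr * self.g_Kr_base

    @property
    def k_NaCa_eff(self) -> float:
        return self.mult_NaCa * self.k_NaCa_base

    @property
    def rtonf(self) -> float:
        return self.R * self.T / self.F

    # serialization ----------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(**dict(d))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


def make_params(mult_CaL: float = 1.0, mult_Ks: float = 1.0,
                mult_Kr: float = 1.0, mult_NaCa: float = 1.0,
                tau_f_scale: float = 0.5, **overrides) -> ModelParams:
    """Build a fully populated endocardial parameter set.

    Raises ``ValueError`` for negative multipliers or non-positive
    ``tau_f_scale``.
    """
    return ModelParams(mult_CaL=mult_CaL, mult_Ks=mult_Ks, mult_Kr=mult_Kr,
                       mult_NaCa=mult_NaCa, tau_f_scale=tau_f_scale, **overrides)


@dataclass
class CellState:
    """One cell: membrane voltage, 12 gates, ion concentrations.

    Gates and ``r_bar`` live in [0, 1]; concentrations are mM.
    """

    V: float = -86.2
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    d: float = 0.0
    f: float = 1.0
    f2: float = 1.0
    f_cass: float = 1.0
    r: float = 0.0
    s: float = 1.0
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    na_i: float = 7.67
    k_i: float = 138.3
    ca_i: float = 0.00007
    ca_ss: float = 0.00007
    ca_sr: float = 1.3
    r_bar: float = 1.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "CellState":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_STATE,):
            raise ValueError(f"state vector must have shape ({N_STATE},)")
        return cls(**{f: float(v[i]) for i, f in enumerate(STATE_FIELDS)})


#: published TP06 initial conditions (near the paced-to-rest point)
TP06_INITIAL_STATE = CellState()


@dataclass
class CurrentSet:
    """All twelve membrane currents [pA/pF] and their sum."""

    i_Na: float
    i_K1: float
    i_to: float
    i_Kr: float
    i_Ks: float
    i_CaL: float
    i_NaCa: float
    i_NaK: float
    i_pCa: float
    i_pK: float
    i_bNa: float
    i_bCa: float
    i_ion: float

    COMPONENTS = ("i_Na", "i_K1", "i_to", "i_Kr", "i_Ks", "i_CaL",
                  "i_NaCa", "i_NaK", "i_pCa", "i_pK", "i_bNa", "i_bCa")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.COMPONENTS + ("i_ion",)}


# ---------------------------------------------------------------------------
# gating kinetics (vectorized reference implementation; also the single
# source for the lookup tables used by the fast integrator)
# ---------------------------------------------------------------------------

def gate_inf_tau(V, p: ModelParams):
    """Steady states and time constants of the 11 voltage gates.

    Returns two dicts keyed by gate name.  ``tau_f`` already includes
    ``tau_f_scale``.  ``f_cass`` is Ca_SS-dependent and handled by
    :func:`fcass_inf_tau`.
    """
    V = np.asarray(V, dtype=float)
    e = np.exp

    inf = {}
    tau = {}

    inf["m"] = 1.0 / (1.0 + e((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + e((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + e((V + 35.0) / 5.0)) + 0.1 / (1.0 + e((V - 50.0) / 200.0))
    tau["m"] = a_m * b_m

    inf["h"] = 1.0 / (1.0 + e((V + 71.55) / 7.43)) ** 2
    a_h = np.where(V >= -40.0, 0.0, 0.057 * e(-(V + 80.0) / 6.8))
    b_h = np.where(
        V >= -40.0,
        0.77 / (0.13 * (1.0 + e(-(V + 10.66) / 11.1))),
        2.7 * e(0.079 * V) + 3.1e5 * e(0.3485 * V),
    )
    tau["h"] = 1.0 / (a_h + b_h)

    inf["j"] = inf["h"]
    a_j = np.where(
        V >= -40.0,
        0.0,
        (-2.5428e4 * e(0.2444 * V) - 6.948e-6 * e(-0.04391 * V)) * (V + 37.78)
        / (1.0 + e(0.311 * (V + 79.23))),
    )
    b_j = np.where(
        V >= -40.0,
        0.6 * e(0.057 * V) / (1.0 + e(-0.1 * (V + 32.0))),
        0.02424 * e(-0.01052 * V) / (1.0 + e(-0.1378 * (V + 40.14))),
    )
    tau["j"] = 1.0 / (a_j + b_j)

    inf["d"] = 1.0 / (1.0 + e((-8.0 - V) / 7.5))
    a_d = 1.4 / (1.0 + e((-35.0 - V) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + e((V + 5.0) / 5.0))
    c_d = 1.0 / (1.0 + e((50.0 - V) / 20.0))
    tau["d"] = a_d * b_d + c_d

    inf["f"] = 1.0 / (1.0 + e((V + 20.0) / 7.0))
    a_f = 1102.5 * e(-((V + 27.0) ** 2) / 225.0)
    b_f = 200.0 / (1.0 + e((13.0 - V) / 10.0))
    c_f = 180.0 / (1.0 + e((V + 30.0) / 10.0)) + 20.0
    tau["f"] = p.tau_f_scale * (a_f + b_f + c_f)

    inf["f2"] = 0.67 / (1.0 + e((V + 35.0) / 7.0)) + 0.33
    a_f2 = 600.0 * e(-((V + 25.0) ** 2) / 170.0)
    b_f2 = 31.0 / (1.0 + e((25.0 - V) / 10.0))
    c_f2 = 16.0 / (1.0 + e((V + 30.0) / 10.0))
    tau["f2"] = a_f2 + b_f2 + c_f2

    inf["r"] = 1.0 / (1.0 + e((20.0 - V) / 6.0))
    tau["r"] = 9.5 * e(-((V + 40.0) ** 2) / 1800.0) + 0.8

    # endocardial s gate
    inf["s"] = 1.0 / (1.0 + e((V + 28.0) / 5.0))
    tau["s"] = 1000.0 * e(-((V + 67.0) ** 2) / 1000.0) + 8.0

    inf["xr1"] = 1.0 / (1.0 + e((-26.0 - V) / 7.0))
    a_xr1 = 450.0 / (1.0 + e((-45.0 - V) / 10.0))
    b_xr1 = 6.0 / (1.0 + e((V + 30.0) / 11.5))
    tau["xr1"] = a_xr1 * b_xr1

    inf["xr2"] = 1.0 / (1.0 + e((V + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + e((-60.0 - V) / 20.0))
    b_xr2 = 1.12 / (1.0 + e((V - 60.0) / 20.0))
    tau["xr2"] = a_xr2 * b_xr2

    inf["xs"] = 1.0 / (1.0 + e((-5.0 - V) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + e((5.0 - V) / 6.0))
    b_xs = 1.0 / (1.0 + e((V - 35.0) / 15.0))
    tau["xs"] = a_xs * b_xs + 80.0

    return inf, tau


def fcass_inf_tau(ca_ss):
    """Subspace-Ca inactivation gate of I_CaL."""
    ca_ss = np.asarray(ca_ss, dtype=float)
    q = 1.0 / (1.0 + (ca_ss / 0.05) ** 2)
    return 0.6 * q + 0.4, 80.0 * q + 2.0


def _cal_driving_factors(V, p: ModelParams):
    """GHK-type driving-force factors A, B with I_CaL = g d f f2 fcass
    (0.25 Ca_SS A - Ca_o B); both tend to 2F at V = 15 mV."""
    V = np.asarray(V, dtype=float)
    z = 2.0 * (V - 15.0) * p.F / (p.R * p.T)
    small = np.abs(z) < 1e-7
    zs = np.where(small, 1.0, z)
    ez = np.exp(zs)
    A = np.where(small, 2.0 * p.F, 2.0 * p.F * zs * ez / (ez - 1.0))
    B = np.where(small, 2.0 * p.F, 2.0 * p.F * zs / (ez - 1.0))
    return A, B


def compute_currents(s, p: ModelParams, *, check: bool = True):
    """All twelve TP06 membrane currents at state ``s`` [pA/pF].

    ``s`` may be a :class:`CellState` or a packed array whose last axis
    has length ``N_STATE`` (vectorized evaluation).
    """
    scalar = isinstance(s, CellState)
    vec = s.to_vector() if scalar else np.asarray(s, dtype=float)
    V = vec[..., 0]
    if check and np.any((V < -150.0) | (V > 150.0) | ~np.isfinite(V)):
        raise FloatingPointError(
            "membrane voltage outside the [-150, 150] mV guard band; "
            "rate functions would overflow")

    m, h, j = vec[..., 1], vec[..., 2], vec[..., 3]
    d, f, f2, fcass = vec[..., 4], vec[..., 5], vec[..., 6], vec[..., 7]
    r, sgate = vec[..., 8], vec[..., 9]
    xr1, xr2, xs = vec[..., 10], vec[..., 11], vec[..., 12]
    na_i, k_i = vec[..., 13], vec[..., 14]
    ca_i, ca_ss = vec[..., 15], vec[..., 16]

    rtonf = p.rtonf
    e_K = rtonf * np.log(p.k_o / k_i)
    e_Na = rtonf * np.log(p.na_o / na_i)
    e_Ks = rtonf * np.log((p.k_o + p.p_KNa * p.na_o) / (k_i + p.p_KNa * na_i))
    e_Ca = 0.5 * rtonf * np.log(p.ca_o / ca_i)

    i_Na = p.g_Na * m ** 3 * h * j * (V - e_Na)

    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (V - e_K - 200.0)))
    b_k1 = (3.0 * np.exp(0.0002 * (V - e_K + 100.0))
            + np.exp(0.1 * (V - e_K - 10.0))) / (1.0 + np.exp(-0.5 * (V - e_K)))
    i_K1 = p.g_K1 * a_k1 / (a_k1 + b_k1) * (V - e_K)

    i_to = p.g_to * r * sgate * (V - e_K)
    i_Kr = p.g_Kr_eff * math.sqrt(p.k_o / 5.4) * xr1 * xr2 * (V - e_K)
    i_Ks = p.g_Ks_eff * xs ** 2 * (V - e_Ks)

    A, B = _cal_driving_factors(V, p)
    i_CaL = p.g_CaL_eff * d * f * f2 * fcass * (0.25 * ca_ss * A - p.ca_o * B)

    vfrt = V * p.F / (p.R * p.T)
    eg = np.exp(p.gamma * vfrt)
    egm1 = np.exp((p.gamma - 1.0) * vfrt)
    i_NaCa = (p.k_NaCa_eff
              * (eg * na_i ** 3 * p.ca_o - egm1 * p.na_o ** 3 * ca_i * p.alpha_naca)
              / ((p.km_Nai ** 3 + p.na_o ** 3) * (p.km_Ca + p.ca_o)
                 * (1.0 + p.k_sat * egm1)))

    rec_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))
    i_NaK = p.p_NaK * (p.k_o / (p.k_o + p.km_K)) * (na_i / (na_i + p.km_Na)) * rec_nak

    i_pCa = p.g_pCa * ca_i / (p.kp_Ca + ca_i)
    i_pK = p.g_pK * (V - e_K) / (1.0 + np.exp((25.0 - V) / 5.98))
    i_bNa = p.g_bNa * (V - e_Na)
    i_bCa = p.g_bCa * (V - e_Ca)

    i_ion = (i_Na + i_K1 + i_to + i_Kr + i_Ks + i_CaL + i_NaCa + i_NaK
             + i_pCa + i_pK + i_bNa + i_bCa)

    if scalar:
        return CurrentSet(*(float(x) for x in
                            (i_Na, i_K1, i_to, i_Kr, i_Ks, i_CaL, i_NaCa,
                             i_NaK, i_pCa, i_pK, i_bNa, i_bCa, i_ion)))
    return {"i_Na": i_Na, "i_K1": i_K1, "i_to": i_to, "i_Kr": i_Kr,
            "i_Ks": i_Ks, "i_CaL": i_CaL, "i_NaCa": i_NaCa, "i_NaK": i_NaK,
            "i_pCa": i_pCa, "i_pK": i_pK, "i_bNa": i_bNa, "i_bCa": i_bCa,
            "i_ion": i_ion}


def rhs(vec, p: ModelParams, i_stim: float = 0.0):
    """Continuous-time derivatives of the packed state vector.

    ``i_stim`` is depolarizing-positive: dV/dt = -(I_ion - i_stim)/C_m.
    Used as the algebraic reference for fixed-point (rest state) checks
    and for cross-validation of the fast stepper.
    """
    vec = np.asarray(vec, dtype=float)
    V = vec[..., 0]
    cur = compute_currents(vec, p, check=False)
    if isinstance(cur, CurrentSet):
        cur = {k: getattr(cur, k) for k in
               CurrentSet.COMPONENTS + ("i_ion",)}

    inf, tau = gate_inf_tau(V, p)
    fc_inf, fc_tau = fcass_inf_tau(vec[..., 16])
    inf["f_cass"], tau["f_cass"] = fc_inf, fc_tau

    out = np.zeros_like(vec)
    out[..., 0] = -(cur["i_ion"] - i_stim) / p.C_m
    for idx, g in enumerate(GATE_FIELDS, start=1):
        out[..., idx] = (inf[g] - vec[..., idx]) / tau[g]

    na_i, k_i = vec[..., 13], vec[..., 14]
    ca_i, ca_ss, ca_sr, r_bar = vec[..., 15], vec[..., 16], vec[..., 17], vec[..., 18]

    k_casr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.ec_sr / ca_sr) ** 2)
    k1 = p.k1_prime / k_casr
    k2 = p.k2_prime * k_casr
    o_rel = k1 * ca_ss ** 2 * r_bar / (p.k3 + k1 * ca_ss ** 2)
    i_rel = p.v_rel * o_rel * (ca_sr - ca_ss)
    i_leak = p.v_leak * (ca_sr - ca_i)
    i_up = p.v_maxup / (1.0 + p.k_up ** 2 / ca_i ** 2)
    i_xfer = p.v_xfer * (ca_ss - ca_i)

    inv_vc_f = 1.0 / (p.v_c * p.F)
    inv_vc_f2 = 1.0 / (2.0 * p.v_c * p.F)
    inv_vss_f2 = 1.0 / (2.0 * p.v_ss * p.F)

    # instantaneous-buffering factors d[Ca]free/d[Ca]total
    bc = 1.0 / (1.0 + p.buf_c * p.k_buf_c / (ca_i + p.k_buf_c) ** 2)
    bss = 1.0 / (1.0 + p.buf_ss * p.k_buf_ss / (ca_ss + p.k_buf_ss) ** 2)
    bsr = 1.0 / (1.0 + p.buf_sr * p.k_buf_sr / (ca_sr + p.k_buf_sr) ** 2)

    out[..., 13] = -(cur["i_Na"] + cur["i_bNa"] + 3.0 * cur["i_NaK"]
                     + 3.0 * cur["i_NaCa"]) * inv_vc_f * p.cap
    out[..., 14] = -(-i_stim + cur["i_K1"] + cur["i_to"] + cur["i_Kr"]
                     + cur["i_Ks"] - 2.0 * cur["i_NaK"] + cur["i_pK"]) * inv_vc_f * p.cap
    out[..., 15] = bc * (-(cur["i_bCa"] + cur["i_pCa"] - 2.0 * cur["i_NaCa"])
                         * inv_vc_f2 * p.cap
                         - (i_up - i_leak) * (p.v_sr / p.v_c) + i_xfer)
    out[..., 16] = bss * (-i_xfer * (p.v_c / p.v_ss) + i_rel * (p.v_sr / p.v_ss)
                          - cur["i_CaL"] * inv_vss_f2 * p.cap)
    out[..., 17] = bsr * (i_up - i_rel - i_leak)
    out[..., 18] = p.k4 * (1.0 - r_bar) - k2 * ca_ss * r_bar
    return out


def step_cell(s: CellState, p: ModelParams, i_stim: float, dt: float,
              *, euler_gates: bool = False) -> CellState:
    """Advance one cell by ``dt`` ms.

    Voltage and concentrations use forward Euler; gates use the
    Rush--Larsen exact-exponential update (or forward Euler when
    ``euler_gates`` is set).  ``i_stim`` is depolarizing-positive
    [pA/pF].  Raises on non-positive or over-large ``dt`` and on NaN in
    the input state (naming the first offending field).
    """
    from . import _kernels

    if not (0.0 < dt <= 0.1):
        raise ValueError(f"dt must be in (0, 0.1] ms, got {dt}")
    vec = s.to_vector()
    if not np.all(np.isfinite(vec)):
        bad = STATE_FIELDS[int(np.flatnonzero(~np.isfinite(vec))[0])]
        raise FloatingPointError(f"non-finite value in state field '{bad}'")

    S = vec.reshape(1, N_STATE)
    _kernels.advance(S, p, dt, n_steps=1,
                     i_stim=np.array([float(i_stim)]),
                     euler_gates=euler_gates)
    return CellState.from_vector(S[0])


def find_rest_state(p: ModelParams, *, settle_ms: float = 1000.0,
                    dt: float = 0.05) -> CellState:
    """Paced-to-rest operating point: the published TP06 initial
    conditions (a paced-steady-state snapshot) relaxed briefly so the
    fast variables sit on the given parameter set.

    Note this is *not* the deep quiescent equilibrium of the
    unstimulated model, which the cell only reaches after many minutes
    (Na_i drains to ~3.5 mM there); physiological and paced studies
    operate around the paced state.  Pass a large ``settle_ms`` (some
    10^6 ms) to obtain the deep equilibrium instead.
    """
    from . import _kernels

    S = TP06_INITIAL_STATE.to_vector().reshape(1, N_STATE)
    n = int(round(settle_ms / dt))
    _kernels.advance(S, p, dt, n_steps=n, i_stim=np.zeros(1))
    return CellState.from_vector(S[0])
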