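"""Fast integration kernels (numba) for the TP06 cell and 2D tissue.

Voltage-dependent gate steady states / time constants and a few pure
voltage factors are pre-tabulated on a 0.05 mV grid between -150 and
150 mV and linearly interpolated inside the kernels; the tables are
built from the reference formulas in :mod:`ead2d.ionic_model`, so the
fast path and the readable path share one source of truth for the
kinetics.

State layout: ``S`` is ``(n_nodes, 19)`` float64 in the order of
``ionic_model.STATE_FIELDS``.  Stimulus currents are
depolarizing-positive [pA/pF].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import ionic_model as im

V_MIN = -150.0
V_MAX = 150.0
V_STEP = 0.05

# table gate order; state index = position+1, skipping f_cass (state 7)
_TABLE_GATES = ("m", "h", "j", "d", "f", "f2", "r", "s", "xr1", "xr2", "xs")
N_GATES_TAB = len(_TABLE_GATES)
# columns: per gate (inf, rl, tau) then the voltage-only factors
COL_REC_NAK = 3 * N_GATES_TAB
COL_REC_PK = COL_REC_NAK + 1
COL_CAL_A = COL_REC_NAK + 2
COL_CAL_B = COL_REC_NAK + 3
COL_EXP_G = COL_REC_NAK + 4
COL_EXP_GM1 = COL_REC_NAK + 5
N_COLS = COL_EXP_GM1 + 1

_FASTMATH = {"contract", "reassoc", "arcp"}


def build_tables(p: im.ModelParams, dt: float) -> np.ndarray:
    """Voltage lookup table for parameter set ``p`` at step ``dt``."""
    V = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
    inf, tau = im.gate_inf_tau(V, p)
    tab = np.empty((V.size, N_COLS), dtype=np.float64)
    for k, g in enumerate(_TABLE_GATES):
        tab[:, 3 * k] = inf[g]
        tab[:, 3 * k + 1] = np.exp(-dt / tau[g])
        tab[:, 3 * k + 2] = tau[g]
    vfrt = V * p.F / (p.R * p.T)
    tab[:, COL_REC_NAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vfrt)
                                 + 0.0353 * np.exp(-vfrt))
    tab[:, COL_REC_PK] = 1.0 / (1.0 + np.exp((25.0 - V) / 5.98))
    A, B = im._cal_driving_factors(V, p)
    tab[:, COL_CAL_A] = A
    tab[:, COL_CAL_B] = B
    tab[:, COL_EXP_G] = np.exp(p.gamma * vfrt)
    tab[:, COL_EXP_GM1] = np.exp((p.gamma - 1.0) * vfrt)
    return tab


def pack_consts(p: im.ModelParams, dt: float) -> np.ndarray:
    """Scalar constants consumed by the kernels."""
    c = np.zeros(46, dtype=np.float64)
    c[0] = p.g_Na
    c[1] = p.g_K1
    c[2] = p.g_to
    c[3] = p.g_Kr_eff * math.sqrt(p.k_o / 5.4)
    c[4] = p.g_Ks_eff
    c[5] = p.g_CaL_eff
    c[6] = p.k_NaCa_eff / ((p.km_Nai ** 3 + p.na_o ** 3) * (p.km_Ca + p.ca_o))
    c[7] = p.p_NaK * p.k_o / (p.k_o + p.km_K)
    c[8] = p.g_pCa
    c[9] = p.g_pK
    c[10] = p.g_bNa
    c[11] = p.g_bCa
    c[12] = p.rtonf
    c[13] = p.na_o
    c[14] = p.k_o
    c[15] = p.ca_o
    c[16] = p.p_KNa
    c[17] = p.km_Na
    c[18] = p.k_sat
    c[19] = p.alpha_naca
    c[20] = p.kp_Ca
    c[21] = p.cap / (p.v_c * p.F)
    c[22] = p.cap / (2.0 * p.v_c * p.F)
    c[23] = p.cap / (2.0 * p.v_ss * p.F)
    c[24] = p.v_sr / p.v_c
    c[25] = p.v_c / p.v_ss
    c[26] = p.v_sr / p.v_ss
    c[27] = p.buf_c
    c[28] = p.k_buf_c
    c[29] = p.buf_sr
    c[30] = p.k_buf_sr
    c[31] = p.buf_ss
    c[32] = p.k_buf_ss
    c[33] = p.v_maxup
    c[34] = p.k_up
    c[35] = p.v_rel
    c[36] = p.v_leak
    c[37] = p.v_xfer
    c[38] = p.k1_prime
    c[39] = p.k2_prime
    c[40] = p.k3
    c[41] = p.k4
    c[42] = p.ec_sr
    c[43] = p.max_sr
    c[44] = p.min_sr
    c[45] = p.C_m
    return c


_table_cache: dict = {}


def get_tables(p: im.ModelParams, dt: float):
    key = (p, float(dt))
    hit = _table_cache.get(key)
    if hit is None:
        hit = (build_tables(p, dt), pack_consts(p, dt))
        if len(_table_cache) > 256:
            _table_cache.clear()
        _table_cache[key] = hit
    return hit


@njit(inline="always", fastmath=_FASTMATH)
def _update_node(S, i, istim, ext, dt, TAB, C, euler_gates):
    """One forward step of node ``i``.  ``ext`` is an extra dV/dt term
    (diffusion).  Returns 0 on success, 1 if V leaves the guard band."""
    V = S[i, 0]
    if not (V >= V_MIN and V <= V_MAX):
        return 1

    x = (V - V_MIN) * (1.0 / V_STEP)
    i0 = int(x)
    w = x - i0

    m = S[i, 1]
    h = S[i, 2]
    j = S[i, 3]
    d = S[i, 4]
    f = S[i, 5]
    f2 = S[i, 6]
    fcass = S[i, 7]
    r = S[i, 8]
    sg = S[i, 9]
    xr1 = S[i, 10]
    xr2 = S[i, 11]
    xs = S[i, 12]
    na_i = S[i, 13]
    k_i = S[i, 14]
    ca_i = S[i, 15]
    ca_ss = S[i, 16]
    ca_sr = S[i, 17]
    r_bar = S[i, 18]

    rtonf = C[12]
    e_k = rtonf * math.log(C[14] / k_i)
    e_na = rtonf * math.log(C[13] / na_i)
    e_ks = rtonf * math.log((C[14] + C[16] * C[13]) / (k_i + C[16] * na_i))
    e_ca = 0.5 * rtonf * math.log(C[15] / ca_i)

    i_na = C[0] * m * m * m * h * j * (V - e_na)

    vek = V - e_k
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (vek - 200.0)))
    b_k1 = (3.0 * math.exp(0.0002 * (vek + 100.0))
            + math.exp(0.1 * (vek - 10.0))) / (1.0 + math.exp(-0.5 * vek))
    i_k1 = C[1] * a_k1 / (a_k1 + b_k1) * vek

    i_to = C[2] * r * sg * vek
    i_kr = C[3] * xr1 * xr2 * vek
    i_ks = C[4] * xs * xs * (V - e_ks)

    cal_a = TAB[i0, COL_CAL_A] + w * (TAB[i0 + 1, COL_CAL_A] - TAB[i0, COL_CAL_A])
    cal_b = TAB[i0, COL_CAL_B] + w * (TAB[i0 + 1, COL_CAL_B] - TAB[i0, COL_CAL_B])
    i_cal = C[5] * d * f * f2 * fcass * (0.25 * ca_ss * cal_a - C[15] * cal_b)

    eg = TAB[i0, COL_EXP_G] + w * (TAB[i0 + 1, COL_EXP_G] - TAB[i0, COL_EXP_G])
    egm1 = TAB[i0, COL_EXP_GM1] + w * (TAB[i0 + 1, COL_EXP_GM1] - TAB[i0, COL_EXP_GM1])
    i_naca = C[6] * (eg * na_i ** 3 * C[15] - egm1 * C[13] ** 3 * ca_i * C[19]) \
        / (1.0 + C[18] * egm1)

    rec_nak = TAB[i0, COL_REC_NAK] + w * (TAB[i0 + 1, COL_REC_NAK] - TAB[i0, COL_REC_NAK])
    i_nak = C[7] * (na_i / (na_i + C[17])) * rec_nak

    i_pca = C[8] * ca_i / (C[20] + ca_i)
    rec_pk = TAB[i0, COL_REC_PK] + w * (TAB[i0 + 1, COL_REC_PK] - TAB[i0, COL_REC_PK])
    i_pk = C[9] * rec_pk * vek
    i_bna = C[10] * (V - e_na)
    i_bca = C[11] * (V - e_ca)

    i_ion = (i_na + i_k1 + i_to + i_kr + i_ks + i_cal + i_naca + i_nak
             + i_pca + i_pk + i_bna + i_bca)

    # --- gates -------------------------------------------------------------
    if euler_gates:
        for k in range(N_GATES_TAB):
            si = k + 1 if k < 6 else k + 2
            g_inf = TAB[i0, 3 * k] + w * (TAB[i0 + 1, 3 * k] - TAB[i0, 3 * k])
            g_tau = TAB[i0, 3 * k + 2] + w * (TAB[i0 + 1, 3 * k + 2] - TAB[i0, 3 * k + 2])
            S[i, si] += dt * (g_inf - S[i, si]) / g_tau
        q = 1.0 / (1.0 + (ca_ss / 0.05) ** 2)
        fc_inf = 0.6 * q + 0.4
        fc_tau = 80.0 * q + 2.0
        S[i, 7] += dt * (fc_inf - fcass) / fc_tau
    else:
        for k in range(N_GATES_TAB):
            si = k + 1 if k < 6 else k + 2
            g_inf = TAB[i0, 3 * k] + w * (TAB[i0 + 1, 3 * k] - TAB[i0, 3 * k])
            rl = TAB[i0, 3 * k + 1] + w * (TAB[i0 + 1, 3 * k + 1] - TAB[i0, 3 * k + 1])
            S[i, si] = g_inf + (S[i, si] - g_inf) * rl
        q = 1.0 / (1.0 + (ca_ss / 0.05) ** 2)
        fc_inf = 0.6 * q + 0.4
        fc_tau = 80.0 * q + 2.0
        S[i, 7] = fc_inf + (fcass - fc_inf) * math.exp(-dt / fc_tau)

    # --- intracellular ion handling (TP06 analytic-buffer updates) ----------
    k_casr = C[43] - (C[43] - C[44]) / (1.0 + (C[42] / ca_sr) ** 2)
    k1 = C[38] / k_casr
    k2 = C[39] * k_casr
    S[i, 18] = r_bar + dt * (C[41] * (1.0 - r_bar) - k2 * ca_ss * r_bar)
    o_rel = k1 * ca_ss * ca_ss * r_bar / (C[40] + k1 * ca_ss * ca_ss)
    i_rel = C[35] * o_rel * (ca_sr - ca_ss)
    i_leak = C[36] * (ca_sr - ca_i)
    i_up = C[33] / (1.0 + (C[34] * C[34]) / (ca_i * ca_i))
    i_xfer = C[37] * (ca_ss - ca_i)

    # SR calcium
    csqn = C[29] * ca_sr / (ca_sr + C[30])
    d_casr = dt * (i_up - i_rel - i_leak)
    b = C[29] - csqn - d_casr - ca_sr + C[30]
    cc = C[30] * (csqn + d_casr + ca_sr)
    S[i, 17] = (math.sqrt(b * b + 4.0 * cc) - b) * 0.5

    # subspace calcium
    ssbuf = C[31] * ca_ss / (ca_ss + C[32])
    d_cass = dt * (-i_xfer * C[25] + i_rel * C[26] - i_cal * C[23])
    b = C[31] - ssbuf - d_cass - ca_ss + C[32]
    cc = C[32] * (ssbuf + d_cass + ca_ss)
    S[i, 16] = (math.sqrt(b * b + 4.0 * cc) - b) * 0.5

    # cytosolic calcium
    cbuf = C[27] * ca_i / (ca_i + C[28])
    d_cai = dt * (-(i_bca + i_pca - 2.0 * i_naca) * C[22]
                  - (i_up - i_leak) * C[24] + i_xfer)
    b = C[27] - cbuf - d_cai - ca_i + C[28]
    cc = C[28] * (cbuf + d_cai + ca_i)
    S[i, 15] = (math.sqrt(b * b + 4.0 * cc) - b) * 0.5

    S[i, 13] = na_i - dt * (i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * C[21]
    S[i, 14] = k_i - dt * (-istim + i_k1 + i_to + i_kr + i_ks
                           - 2.0 * i_nak + i_pk) * C[21]

    S[i, 0] = V + dt * (ext - (i_ion - istim) / C[45])
    return 0


@njit(fastmath=_FASTMATH)
def _run_cells(S, istim, dt, n_steps, TAB, C, euler_gates):
    """Advance ``n_steps`` with a constant per-node stimulus.  Returns
    -1 on success, else ``node_index`` of the first failing node."""
    n = S.shape[0]
    for _ in range(n_steps):
        for i in range(n):
            if _update_node(S, i, istim[i], 0.0, dt, TAB, C, euler_gates):
                return i
    return -1


@njit(fastmath=_FASTMATH)
def _run_tissue(S, ny, nx, conn_x, conn_y, istim, d_over_dx2, dt, n_steps,
                TAB, C, euler_gates, diffusion_only):
    """Advance a 2D sheet ``n_steps`` with constant stimulus field.

    ``conn_x[y, x]`` couples node (y,x) to (y,x+1); ``conn_y[y, x]``
    couples (y,x) to (y+1,x).  Missing/masked edges contribute zero flux
    (Neumann boundary and barriers in one mechanism).  Returns -1 or the
    flat index of the first failing node.
    """
    n = ny * nx
    lap = np.empty(n, dtype=np.float64)
    for _ in range(n_steps):
        for y in range(ny):
            base = y * nx
            for x in range(nx):
                i = base + x
                v = S[i, 0]
                acc = 0.0
                if x > 0 and conn_x[y, x - 1]:
                    acc += S[i - 1, 0] - v
                if x < nx - 1 and conn_x[y, x]:
                    acc += S[i + 1, 0] - v
                if y > 0 and conn_y[y - 1, x]:
                    acc += S[i - nx, 0] - v
                if y < ny - 1 and conn_y[y, x]:
                    acc += S[i + nx, 0] - v
                lap[i] = acc
        if diffusion_only:
            for i in range(n):
                S[i, 0] += dt * d_over_dx2 * lap[i]
        else:
            for i in range(n):
                if _update_node(S, i, istim[i], d_over_dx2 * lap[i],
                                dt, TAB, C, euler_gates):
                    return i
    return -1


class IntegrationError(RuntimeError):
    """Raised when the integrator leaves the physiological guard band."""

    def __init__(self, msg, node=None, field=None):
        super().__init__(msg)
        self.node = node
        self.field = field


def _fail(S, i, ny=None, nx=None):
    vec = S[i]
    bad = "V"
    for k, name in enumerate(im.STATE_FIELDS):
        if not np.isfinite(vec[k]):
            bad = name
            break
    where = f"node {i}"
    if ny is not None:
        where = f"node (y={i // nx}, x={i % nx})"
    raise IntegrationError(
        f"integration failure at {where}: field '{bad}' left the guard "
        f"band (V = {vec[0]!r})", node=i, field=bad)


def advance(S: np.ndarray, p: im.ModelParams, dt: float, n_steps: int,
            i_stim: np.ndarray, euler_gates: bool = False) -> None:
    """Advance a batch of uncoupled cells in place."""
    TAB, C = get_tables(p, dt)
    bad = _run_cells(S, np.asarray(i_stim, dtype=np.float64), dt,
                     n_steps, TAB, C, euler_gates)
    if bad >= 0:
        _fail(S, bad)


def advance_tissue(S: np.ndarray, ny: int, nx: int, conn_x: np.ndarray,
                   conn_y: np.ndarray, p: im.ModelParams, dt: float,
                   n_steps: int, i_stim: np.ndarray, d_over_dx2: float,
                   euler_gates: bool = False,
                   diffusion_only: bool = False) -> None:
    """Advance a coupled 2D sheet in place (constant stimulus field)."""
    TAB, C = get_tables(p, dt)
    bad = _run_tissue(S, ny, nx, conn_x, conn_y,
                      np.asarray(i_stim, dtype=np.float64), d_over_dx2,
                      dt, n_steps, TAB, C, euler_gates, diffusion_only)
    if bad >= 0:
        _fail(S, bad, ny, nx)
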