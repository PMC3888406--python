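"""Analytic AP traces and 2D voltage/gate movies with known labels.

These fixtures exercise every analysis operator without running the PDE
solver: template action potentials (normal, k-EAD, oscillatory), plane /
spiral / target-wave movies, pure phase-gradient oscillation fields, and
seeded noise movies.  Gate-product channels are synthesized consistently
with the declared Na/Ca ground truth, and every fixture carries a truth
record; the analysis pipeline must reproduce it exactly.

Physiological realism is intentionally limited to what the classifier
rules require (voltage floors, upstroke shapes, phase structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .single_cell import APTrace
from .tissue2d import FrameSeries

__all__ = ["FixtureSpec", "make_ap_trace", "make_movie", "AP_KINDS",
           "MOVIE_KINDS"]

AP_KINDS = ("normal_ap", "ead_ap", "osc_ap")
MOVIE_KINDS = ("plane_movie", "spiral_movie", "target_movie",
               "phase_osc_movie", "noise_movie")

REST_V = -86.0
PEAK_V = 20.0


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic (seeded) specification of one fixture."""

    kind: str
    # trace fixtures
    k_eads: int = 0
    ead_height: float = 20.0       # mV
    duration: float = 5000.0       # ms
    sample_ms: float = 1.0
    # movie fixtures
    ny: int = 40
    nx: int = 40
    dx: float = 0.25               # mm
    frame_interval: float = 2.0    # ms
    f_hz: float = 6.0              # oscillation / rotation frequency
    n_arms: int = 1                # spiral arms
    n_spirals: int = 1             # distinct spiral cores
    wavelength: float = 20.0       # mm (spiral pitch)
    speed: float = 0.5             # mm/ms (plane/target waves)
    apd: float = 200.0             # ms, template pulse duration
    amplitude: float = 12.0        # mV (phase_osc_movie)
    baseline: float = -30.0        # mV (phase_osc_movie)
    na_led: bool = True            # ground truth of the wavefronts
    die_at: Optional[float] = None  # ms; movie decays to rest after this
    barrier_block: Optional[int] = None  # emulate an imposed barrier grid
    seed: int = 0

    def __post_init__(self):
        if self.kind not in AP_KINDS + MOVIE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "osc_ap" and self.k_eads > 0:
            raise ValueError("osc_ap cannot carry EAD humps")
        if self.kind == "ead_ap" and self.k_eads < 1:
            raise ValueError("ead_ap needs k_eads >= 1")


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ap_template(t, t0=10.0, apd=300.0, k_eads=0, ead_height=20.0):
    """Piecewise-smooth AP: upstroke to +20 mV, sagging plateau, optional
    raised-cosine EAD humps above -40 mV, repolarization to rest."""
    up = 2.0
    plateau_end = t0 + up + apd
    rep = 80.0
    v = np.full_like(t, REST_V, dtype=float)
    v += (PEAK_V - REST_V) * _smoothstep((t - t0) / up)
    # plateau sag from +20 toward -30 mV
    sag = _smoothstep((t - (t0 + up)) / apd)
    v -= 50.0 * sag
    # repolarization to rest
    v += (REST_V - (PEAK_V - 50.0)) * _smoothstep((t - plateau_end) / rep)
    for k in range(k_eads):
        # humps riding on the late plateau, base voltage in (-40, 0)
        c = t0 + up + apd * (0.55 + 0.4 * (k + 0.5) / k_eads)
        w = apd * 0.4 / k_eads * 0.8
        hump = ead_height * 0.5 * (1.0 + np.cos(np.pi * (t - c) / (w / 2.0)))
        hump[np.abs(t - c) > w / 2.0] = 0.0
        v += hump
    return v


def make_ap_trace(spec: FixtureSpec):
    """Template trace plus its ground-truth label."""
    if spec.kind not in AP_KINDS:
        raise ValueError(f"{spec.kind!r} is not a trace fixture")
    t = np.arange(0.0, spec.duration + spec.sample_ms / 2, spec.sample_ms)
    if spec.kind == "normal_ap":
        v = _ap_template(t)
        label = "NORMAL"
    elif spec.kind == "ead_ap":
        v = _ap_template(t, k_eads=spec.k_eads, ead_height=spec.ead_height)
        label = "EAD"
    else:  # osc_ap: never drops below -60 mV
        v = np.full_like(t, REST_V)
        ramp = _smoothstep((t - 10.0) / 2.0)
        target = -30.0 + 15.0 * np.sin(2.0 * np.pi * spec.f_hz * (t - 12.0)
                                       / 1000.0)
        v = REST_V + (target - REST_V) * ramp
        label = "OSCILLATORY"
    tr = APTrace(t=t, V=v, stim_onsets=(10.0,), stim_amplitude=20.0,
                 stim_duration=2.0, meta={"fixture": spec.kind,
                                          "truth": label})
    return tr, label


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def _pulse_profile(phase_01, duty=0.35):
    """Map cyclic phase in [0,1) to an AP-like pulse: sharp upstroke,
    plateau, smooth return to rest."""
    ph = np.asarray(phase_01)
    up = _smoothstep(ph / 0.02)
    down = _smoothstep((ph - duty) / 0.12)
    return REST_V + (PEAK_V - REST_V) * (up - down).clip(0.0, 1.0)


def _gate_channels(V, na_led, floor):
    """Na availability / Ca openness consistent with the declared truth.

    Na-led movies: availability is high whenever the node sits near its
    (deep) diastolic floor and collapses after excitation.  Ca-led
    movies: availability is negligible everywhere.
    """
    if na_led:
        na = np.full(V.shape, 0.5, dtype=np.float32)
    else:
        na = np.full(V.shape, 1e-6, dtype=np.float32)
    ca = np.where(V > -40.0, 0.6, 1e-3).astype(np.float32)
    return na, ca


def _compartment_of(ny, nx, block):
    """Index map of barrier compartments (lattice pitch ``block``)."""
    yy = np.arange(ny) // block
    xx = np.arange(nx) // block
    return yy[:, None], xx[None, :]


def make_movie(spec: FixtureSpec):
    """Analytic movie (V + gate products) plus its truth record."""
    if spec.kind not in MOVIE_KINDS:
        raise ValueError(f"{spec.kind!r} is not a movie fixture")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.frame_interval / 2,
                  spec.frame_interval)
    ys = np.arange(spec.ny) * spec.dx
    xs = np.arange(spec.nx) * spec.dx
    X = xs[None, None, :]
    Y = ys[None, :, None]
    T = t[:, None, None]
    truth = {"kind": spec.kind, "seed": spec.seed, "na_led": spec.na_led,
             "f_hz": spec.f_hz}

    if spec.kind == "noise_movie":
        V = REST_V + 5.0 * rng.standard_normal((t.size, spec.ny, spec.nx))
        V = V.astype(np.float32)
        na, ca = _gate_channels(V, spec.na_led, REST_V)
        truth["label"] = "NOISE"
        return FrameSeries(times=t, V=V, na=na, ca=ca, dx=spec.dx,
                           meta={"fixture": spec.kind, "truth": truth}), truth

    period = 1000.0 / spec.f_hz

    if spec.kind == "phase_osc_movie":
        # pure phase gradient: no diffusive content whatsoever
        ang = rng.uniform(0.0, 2.0 * np.pi)
        gmax = 2.0 * np.pi / (4.0 * max(xs[-1], ys[-1]))  # one cycle / 4 domains
        gx, gy = gmax * np.cos(ang), gmax * np.sin(ang)
        phi = gx * X + gy * Y
        V = spec.baseline + spec.amplitude * np.cos(
            2.0 * np.pi * T / period - phi)
        V = V.astype(np.float32)
        na = np.full(V.shape, 1e-6, dtype=np.float32)
        ca = (0.5 + 0.4 * np.cos(2.0 * np.pi * T / period - phi)).astype(np.float32)
        truth.update(label="OSC", verdict="PHASE_WAVES")
        return FrameSeries(times=t, V=V, na=na, ca=ca, dx=spec.dx,
                           meta={"fixture": spec.kind, "truth": truth}), truth

    if spec.kind == "plane_movie":
        tau = T - X / spec.speed - 5.0
        if spec.k_eads:
            # AP template with EAD humps riding the gentle plateau sag
            V = _ap_template(tau, t0=0.0, apd=spec.apd,
                             k_eads=spec.k_eads, ead_height=spec.ead_height)
        else:
            V = _pulse_profile(np.clip(tau / (spec.apd / 0.35), 0, 0.999))
            V = np.where(tau < 0, REST_V, V)
        # the plane wave has no y-dependence; expand to the full grid
        V = (V + np.zeros((1, spec.ny, 1))).astype(np.float32)
        if not spec.na_led:
            V = np.maximum(V, -55.0).astype(np.float32)  # elevated floor
        na, ca = _gate_channels(V, spec.na_led, REST_V)
        truth.update(label="PLAIN_PROPAGATION" if not spec.k_eads
                     else "NO_SUSTAINED_EAD")
        return FrameSeries(times=t, V=V, na=na, ca=ca, dx=spec.dx,
                           meta={"fixture": spec.kind, "truth": truth}), truth

    if spec.kind == "spiral_movie":
        if spec.n_spirals == 1:
            cx, cy = xs[-1] / 2.0, ys[-1] / 2.0
            theta = np.arctan2(Y - cy, X - cx)
            rr = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
            phi = spec.n_arms * theta + 2.0 * np.pi * rr / spec.wavelength
        else:
            # several cores with alternating chirality
            phi = np.zeros((1, spec.ny, spec.nx))
            for k in range(spec.n_spirals):
                cx = rng.uniform(0.25, 0.75) * xs[-1]
                cy = rng.uniform(0.25, 0.75) * ys[-1]
                q = 1 if k % 2 == 0 else -1
                phi = phi + q * np.arctan2(Y - cy, X - cx)
            rr = np.sqrt((X - xs[-1] / 2) ** 2 + (Y - ys[-1] / 2) ** 2)
            phi = phi + 2.0 * np.pi * rr / spec.wavelength
        ph01 = ((T / period - phi / (2.0 * np.pi)) % 1.0)
        V = _pulse_profile(ph01)
        if not spec.na_led:
            # Ca waves: elevated floor (-50 mV), reduced amplitude
            V = -50.0 + (V - REST_V) * 0.5
        V = V.astype(np.float32)
        na, ca = _gate_channels(V, spec.na_led,
                                REST_V if spec.na_led else -50.0)
        label = "SINGLE_SPIRAL" if (spec.n_spirals == 1 and spec.n_arms == 1) \
            else ("SF_b" if spec.na_led else "SF_a")
        if spec.die_at is not None:
            decay = _smoothstep((T - spec.die_at) / 200.0)
            rest = REST_V if spec.na_led else REST_V
            V = (V * (1 - decay) + rest * decay).astype(np.float32)
            na = np.where(V < -70.0, 0.5 if spec.na_led else 1e-6,
                          na).astype(np.float32)
            label = "SELF_TERMINATED_SFa"
        truth.update(label=label, verdict="TRIGGER_WAVES")
        return FrameSeries(times=t, V=V, na=na, ca=ca, dx=spec.dx,
                           meta={"fixture": spec.kind, "truth": truth}), truth

    # target_movie: concentric trigger waves from a centre source
    cx = rng.uniform(0.35, 0.65) * xs[-1]
    cy = rng.uniform(0.35, 0.65) * ys[-1]
    rr = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    tau = T - rr / spec.speed
    ph01 = (tau / period) % 1.0
    V = np.where(tau >= 0, _pulse_profile(ph01), REST_V)
    if spec.barrier_block:
        # trigger waves are absorbed: only the source compartment stays
        # active after the barrier is imposed
        iy, ix = _compartment_of(spec.ny, spec.nx, spec.barrier_block)
        comp = (iy == int(cy / spec.dx) // spec.barrier_block) & \
               (ix == int(cx / spec.dx) // spec.barrier_block)
        V = np.where(comp[None, :, :], V, REST_V)
    if spec.die_at is not None:
        decay = _smoothstep((T - spec.die_at) / 200.0)
        V = V * (1 - decay) + REST_V * decay
    V = V.astype(np.float32)
    na, ca = _gate_channels(V, spec.na_led, REST_V)
    truth.update(label="TARGET", verdict="TRIGGER_WAVES")
    return FrameSeries(times=t, V=V, na=na, ca=ca, dx=spec.dx,
                       meta={"fixture": spec.kind, "truth": truth}), truth
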