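"""2D monodomain tissue: explicit solver, protocols, barrier grids.

The tissue is an isotropic monodomain sheet,

    dV/dt = D * laplacian(V) - (I_ion + I_stim) / C_m,

integrated with forward Euler on a regular grid (5-point Laplacian,
no-flux Neumann boundaries).  Coupling is defined on *edges*: a boolean
mask per nearest-neighbour edge, where a masked (non-conducting) edge
contributes zero flux.  Domain boundaries and internal barriers are
therefore the same mechanism.

Wave-initiation protocols:

* **P1** - one stimulus to a 6-node-wide strip on the left edge; a plane
  wave crosses the domain.
* **P2** - the S1-S2 cross-field protocol: S1 as in P1, and once the S1
  front has passed mid-domain *and* the lower-left quarter has recovered,
  that quarter is stimulated, launching a single spiral.
* **paced** - P1 strip re-stimulated periodically during a pacing epoch,
  then free run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time as _time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .ionic_model import N_STATE, ModelParams, make_params
from .single_cell import _rest_vector

__all__ = [
    "TissueConfig", "TissueState", "FrameSeries", "CouplingMask",
    "BarrierSpec", "ProtocolError", "laplacian5", "step_tissue",
    "protocol_p1", "protocol_p2", "protocol_paced", "apply_barrier_grid",
    "run_simulation", "RunResult",
]

log = logging.getLogger(__name__)


class ProtocolError(RuntimeError):
    pass


@dataclass
class CouplingMask:
    """Per-edge conduction flags.  ``conn_x[y, x]`` couples (y, x) to
    (y, x+1); ``conn_y[y, x]`` couples (y, x) to (y+1, x).  Edges on the
    domain boundary do not exist (no-flux)."""

    conn_x: np.ndarray  # (ny, nx-1) uint8
    conn_y: np.ndarray  # (ny-1, nx) uint8

    @classmethod
    def full(cls, ny: int, nx: int) -> "CouplingMask":
        return cls(conn_x=np.ones((ny, nx - 1), dtype=np.uint8),
                   conn_y=np.ones((ny - 1, nx), dtype=np.uint8))

    def copy(self) -> "CouplingMask":
        return CouplingMask(self.conn_x.copy(), self.conn_y.copy())


def laplacian5(V: np.ndarray, dx: float,
               mask: Optional[CouplingMask] = None) -> np.ndarray:
    """5-point Laplacian with zero-flux boundaries and edge barriers.

    ``V`` is (ny, nx) in mV, ``dx`` in mm; the result has units
    mV/mm^2.  A missing or masked edge contributes its centre value
    (zero flux across the edge).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("field must be 2D")
    ny, nx = V.shape
    if mask is None:
        mask = CouplingMask.full(ny, nx)
    if mask.conn_x.shape != (ny, nx - 1) or mask.conn_y.shape != (ny - 1, nx):
        raise ValueError("coupling mask shape does not match field")
    acc = np.zeros_like(V)
    cx = mask.conn_x.astype(bool)
    cy = mask.conn_y.astype(bool)
    dE = np.where(cx, V[:, 1:] - V[:, :-1], 0.0)
    acc[:, :-1] += dE
    acc[:, 1:] -= dE
    dS = np.where(cy, V[1:, :] - V[:-1, :], 0.0)
    acc[:-1, :] += dS
    acc[1:, :] -= dS
    return acc / dx ** 2


@dataclass(frozen=True)
class BarrierSpec:
    """Square-lattice non-conducting barrier grid."""

    block: int                 # lattice pitch [nodes]
    thickness: int = 1         # edge planes cut per lattice line
    start_time: float = 0.0    # ms; barriers imposed at this time
    mode: str = "mask"         # "mask" (non-conducting edges) or
    #                            "refractory" (sustained stimulation)
    refractory_amplitude: float = 20.0

    def __post_init__(self):
        if self.block < 4:
            raise ValueError("barrier block must be >= 4 nodes")
        if self.thickness >= self.block:
            raise ValueError("barrier thickness must be < block")
        if self.mode not in ("mask", "refractory"):
            raise ValueError(f"unknown barrier mode {self.mode!r}")


@dataclass
class TissueConfig:
    """Run configuration for one 2D simulation."""

    nx: int = 600
    ny: int = 600
    dx: float = 0.25            # mm
    dt: float = 0.02            # ms
    D: float = 0.00154          # cm^2/ms
    duration: float = 1000.0    # ms
    frame_interval: float = 5.0  # ms
    protocol: str = "p1"        # p1 | p2 | paced | none
    stim_amplitude: float = 20.0  # pA/pF, depolarizing-positive
    stim_duration: float = 2.0    # ms
    strip_width: int = 6          # P1 strip width [nodes]
    strip_height: Optional[int] = None   # default: full left edge
    s2_quarter: str = "bottom-left"
    pacing_period: float = 1000.0  # ms (paced protocol)
    pacing_epoch: float = 3000.0   # ms of periodic stimulation
    mult_CaL: float = 1.0
    mult_Ks: float = 1.0
    mult_Kr: float = 1.0
    mult_NaCa: float = 1.0
    tau_f_scale: float = 0.5
    barrier: Optional[BarrierSpec] = None
    record_gates: bool = True
    euler_gates: bool = False
    diffusion_only: bool = False   # test mode: pure diffusion, no kinetics
    control_interval: float = 1.0  # ms; protocol/stimulus update period

    def __post_init__(self):
        if self.nx < 10 or self.ny < 10:
            raise ValueError("grid must be at least 10x10 nodes")
        dx_cm = self.dx / 10.0
        if self.D > 0 and self.dt > dx_cm ** 2 / (4.0 * self.D) + 1e-12:
            raise ValueError(
                f"explicit stability violated: dt={self.dt} > dx^2/(4D)="
                f"{dx_cm ** 2 / (4.0 * self.D):.4g} ms")
        for iv, name in ((self.frame_interval, "frame_interval"),
                         (self.control_interval, "control_interval")):
            if abs(round(iv / self.dt) * self.dt - iv) > 1e-9:
                raise ValueError(f"{name} must be a multiple of dt")
        if abs(round(self.frame_interval / self.control_interval)
               * self.control_interval - self.frame_interval) > 1e-9:
            raise ValueError(
                "frame_interval must be a multiple of control_interval")
        if self.protocol not in ("p1", "p2", "paced", "none"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "paced" and self.pacing_period < 300.0:
            raise ValueError("pacing period must be >= 300 ms")
        if self.strip_width >= self.nx:
            raise ValueError("P1 strip exceeds the domain")
        if self.strip_height is not None and self.strip_height > self.ny:
            raise ValueError("P1 strip exceeds the domain")

    def params(self) -> ModelParams:
        return make_params(mult_CaL=self.mult_CaL, mult_Ks=self.mult_Ks,
                           mult_Kr=self.mult_Kr, mult_NaCa=self.mult_NaCa,
                           tau_f_scale=self.tau_f_scale)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class TissueState:
    """Full model state on the grid plus the coupling mask."""

    S: np.ndarray              # (ny*nx, N_STATE) float64
    mask: CouplingMask
    ny: int
    nx: int
    time: float = 0.0

    @classmethod
    def at_rest(cls, cfg: TissueConfig,
                params: Optional[ModelParams] = None) -> "TissueState":
        p = params if params is not None else cfg.params()
        rest = _rest_vector(p)
        S = np.tile(rest, (cfg.ny * cfg.nx, 1))
        return cls(S=S, mask=CouplingMask.full(cfg.ny, cfg.nx),
                   ny=cfg.ny, nx=cfg.nx)

    @property
    def V(self) -> np.ndarray:
        return self.S[:, 0].reshape(self.ny, self.nx)

    def field(self, state_index: int) -> np.ndarray:
        return self.S[:, state_index].reshape(self.ny, self.nx)

    def na_availability(self) -> np.ndarray:
        """Product m^3 h j (sodium-channel openness)."""
        m, h, j = self.S[:, 1], self.S[:, 2], self.S[:, 3]
        return (m ** 3 * h * j).reshape(self.ny, self.nx)

    def ca_gate_openness(self) -> np.ndarray:
        """Product d f f2 fCass (L-type calcium gate openness)."""
        d, f, f2, fc = self.S[:, 4], self.S[:, 5], self.S[:, 6], self.S[:, 7]
        return (d * f * f2 * fc).reshape(self.ny, self.nx)

    def copy(self) -> "TissueState":
        return TissueState(S=self.S.copy(), mask=self.mask.copy(),
                           ny=self.ny, nx=self.nx, time=self.time)


def step_tissue(ts: TissueState, cfg: TissueConfig,
                i_stim: Optional[np.ndarray] = None, n_steps: int = 1,
                params: Optional[ModelParams] = None) -> TissueState:
    """Advance the tissue ``n_steps`` of ``cfg.dt`` in place and return it.

    ``i_stim`` is a (ny, nx) depolarizing-positive stimulus field held
    constant over the steps.
    """
    p = params if params is not None else cfg.params()
    stim = (np.zeros(ts.ny * ts.nx) if i_stim is None
            else np.asarray(i_stim, dtype=float).reshape(ts.ny * ts.nx))
    d_over_dx2 = cfg.D / (cfg.dx / 10.0) ** 2
    _kernels.advance_tissue(ts.S, ts.ny, ts.nx, ts.mask.conn_x,
                            ts.mask.conn_y, p, cfg.dt, n_steps, stim,
                            d_over_dx2, euler_gates=cfg.euler_gates,
                            diffusion_only=cfg.diffusion_only)
    ts.time += n_steps * cfg.dt
    return ts


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

class _Protocol:
    """A stimulus schedule: maps (state, time) -> stimulus field."""

    def stim_field(self, ts: TissueState, t: float, cfg: TissueConfig):
        raise NotImplementedError

    def check(self, ts: TissueState, t: float, cfg: TissueConfig):
        """Called every control interval; may raise ProtocolError."""

    def events(self) -> list:
        return list(getattr(self, "_events", []))


def _strip_mask(cfg: TissueConfig) -> np.ndarray:
    m = np.zeros((cfg.ny, cfg.nx), dtype=bool)
    h = cfg.ny if cfg.strip_height is None else cfg.strip_height
    m[:h, : cfg.strip_width] = True
    return m


class P1(_Protocol):
    """Single plane-wave stimulus at the left edge."""

    def __init__(self, onsets=(0.0,)):
        self.onsets = tuple(onsets)
        self._events = []
        self._fired = set()

    def stim_field(self, ts, t, cfg):
        for on in self.onsets:
            if on <= t < on + cfg.stim_duration:
                if on not in self._fired:
                    self._fired.add(on)
                    self._events.append({"t": float(t), "event": "stimulus",
                                         "onset": float(on)})
                f = np.zeros((cfg.ny, cfg.nx))
                f[_strip_mask(cfg)] = cfg.stim_amplitude
                return f
        return None

    @property
    def last_onset(self) -> float:
        return max(self.onsets)


class P2(_Protocol):
    """S1-S2 cross-field stimulation producing one spiral.

    S2 fires automatically once the S1 front has crossed mid-domain and
    the S2 quarter has recovered below the recovery threshold, i.e. just
    behind the receding waveback, where propagation is unidirectionally
    blocked toward the still-refractory side.
    """

    def __init__(self, recovery_threshold: float = -70.0,
                 front_threshold: float = -30.0):
        self.recovery_threshold = recovery_threshold
        self.front_threshold = front_threshold
        self.s1 = P1()
        self.front_crossed = False
        self.s2_time: Optional[float] = None
        self._events = []

    def _quarter(self, cfg) -> np.ndarray:
        m = np.zeros((cfg.ny, cfg.nx), dtype=bool)
        if cfg.s2_quarter == "bottom-left":
            m[: cfg.ny // 2, : cfg.nx // 2] = True
        elif cfg.s2_quarter == "top-left":
            m[cfg.ny // 2:, : cfg.nx // 2] = True
        else:
            raise ValueError(f"unknown s2_quarter {cfg.s2_quarter!r}")
        return m

    def stim_field(self, ts, t, cfg):
        f = self.s1.stim_field(ts, t, cfg)
        if f is not None:
            return f
        if self.s2_time is not None and \
                self.s2_time <= t < self.s2_time + cfg.stim_duration:
            f = np.zeros((cfg.ny, cfg.nx))
            f[self._quarter(cfg)] = cfg.stim_amplitude
            return f
        return None

    def check(self, ts, t, cfg):
        if self.s2_time is not None:
            return
        V = ts.V
        active_cols = np.flatnonzero((V > self.front_threshold).any(axis=0))
        if not self.front_crossed:
            if active_cols.size and active_cols[-1] >= cfg.nx // 2:
                self.front_crossed = True
                self._events.append({"t": float(t), "event": "front_crossed_mid"})
            elif t > cfg.stim_duration + 50.0 and not active_cols.size:
                raise ProtocolError("S1 failed to propagate")
        else:
            if V[self._quarter(cfg)].max() < self.recovery_threshold:
                self.s2_time = t
                self._events.append({"t": float(t), "event": "s2_fired"})

    def events(self):
        return self.s1.events() + list(self._events)

    @property
    def last_onset(self) -> float:
        return self.s2_time if self.s2_time is not None else 0.0


def protocol_p1(cfg: TissueConfig) -> P1:
    return P1()


def protocol_p2(cfg: TissueConfig) -> P2:
    return P2()


def protocol_paced(cfg: TissueConfig, period: Optional[float] = None) -> P1:
    per = cfg.pacing_period if period is None else period
    if per < 300.0:
        raise ValueError("pacing period must be >= 300 ms")
    onsets = np.arange(0.0, cfg.pacing_epoch, per)
    return P1(onsets=tuple(onsets))


class _NoStim(_Protocol):
    def stim_field(self, ts, t, cfg):
        return None

    last_onset = 0.0


def make_protocol(cfg: TissueConfig) -> _Protocol:
    if cfg.protocol == "p1":
        return protocol_p1(cfg)
    if cfg.protocol == "p2":
        return protocol_p2(cfg)
    if cfg.protocol == "paced":
        return protocol_paced(cfg)
    return _NoStim()


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------

def apply_barrier_grid(ts: TissueState, block: int,
                       thickness: int = 1) -> TissueState:
    """Cut a square lattice of non-conducting edges of pitch ``block``.

    Cell states are untouched; only the coupling mask changes.  The
    lattice lines sit between columns/rows k*block-1 and k*block.
    """
    BarrierSpec(block=block, thickness=thickness)  # validate
    for k in range(block, ts.nx, block):
        for off in range(thickness):
            c = k - 1 + off
            if c < ts.nx - 1:
                ts.mask.conn_x[:, c] = 0
    for k in range(block, ts.ny, block):
        for off in range(thickness):
            r = k - 1 + off
            if r < ts.ny - 1:
                ts.mask.conn_y[r, :] = 0
    return ts


def barrier_lattice_mask(ny: int, nx: int, block: int,
                         thickness: int = 1) -> np.ndarray:
    """Node mask of the lattice lines (for refractory-mode barriers and
    for excluding barrier nodes in analysis)."""
    m = np.zeros((ny, nx), dtype=bool)
    for k in range(block, nx, block):
        m[:, k - 1: k - 1 + thickness] = True
    for k in range(block, ny, block):
        m[k - 1: k - 1 + thickness, :] = True
    return m


# ---------------------------------------------------------------------------
# frame capture and the run driver
# ---------------------------------------------------------------------------

@dataclass
class FrameSeries:
    """Time-ordered stack of sampled 2D fields with grid/time metadata."""

    times: np.ndarray            # (nt,) ms
    V: np.ndarray                # (nt, ny, nx) float32 mV
    na: Optional[np.ndarray]     # m^3 h j at frame times
    ca: Optional[np.ndarray]     # d f f2 fCass
    dx: float                    # mm
    meta: dict = field(default_factory=dict)
    stim_log: list = field(default_factory=list)

    @property
    def ny(self) -> int:
        return self.V.shape[1]

    @property
    def nx(self) -> int:
        return self.V.shape[2]

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def node_trace(self, y: int, x: int) -> np.ndarray:
        return self.V[:, y, x].astype(float)

    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("V", data=self.V, compression="gzip")
            if self.na is not None:
                fh.create_dataset("na", data=self.na, compression="gzip")
            if self.ca is not None:
                fh.create_dataset("ca", data=self.ca, compression="gzip")
            fh.attrs["dx"] = self.dx
            fh.attrs["meta"] = json.dumps(self.meta)
            fh.attrs["stim_log"] = json.dumps(self.stim_log)

    def save_vtk_frame(self, index: int, path) -> None:
        """One frame as legacy-ASCII VTK structured points (for ParaView
        and friends)."""
        fields = {"V": self.V[index]}
        if self.na is not None:
            fields["na_availability"] = self.na[index]
        if self.ca is not None:
            fields["ca_openness"] = self.ca[index]
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n"
                     f"ead2d frame t={self.times[index]:.3f} ms\n"
                     "ASCII\nDATASET STRUCTURED_POINTS\n"
                     f"DIMENSIONS {self.nx} {self.ny} 1\n"
                     "ORIGIN 0 0 0\n"
                     f"SPACING {self.dx} {self.dx} 1\n"
                     f"POINT_DATA {self.nx * self.ny}\n")
            for name, data in fields.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, data.reshape(-1, 1), fmt="%.4f")

    @classmethod
    def load_h5(cls, path) -> "FrameSeries":
        import h5py
        with h5py.File(path, "r") as fh:
            return cls(times=fh["times"][:], V=fh["V"][:],
                       na=fh["na"][:] if "na" in fh else None,
                       ca=fh["ca"][:] if "ca" in fh else None,
                       dx=float(fh.attrs["dx"]),
                       meta=json.loads(fh.attrs.get("meta", "{}")),
                       stim_log=json.loads(fh.attrs.get("stim_log", "[]")))


@dataclass
class RunResult:
    frames: FrameSeries
    state: TissueState
    log: dict
    config: TissueConfig

    @property
    def last_stim_time(self) -> float:
        stims = [e["t"] for e in self.frames.stim_log
                 if e["event"] in ("stimulus", "s2_fired")]
        return max(stims) if stims else 0.0


def run_simulation(cfg: TissueConfig,
                   initial: Optional[TissueState] = None,
                   protocol: Optional[_Protocol] = None,
                   progress: bool = False) -> RunResult:
    """Execute one configured run and capture frames.

    Deterministic: identical configs yield bit-identical frame stacks.
    On integrator failure the partial frames are preserved and the log
    carries ``aborted: True`` plus the failing node.
    """
    p = cfg.params()
    ts = initial if initial is not None else TissueState.at_rest(cfg, p)
    proto = protocol if protocol is not None else make_protocol(cfg)

    steps_per_control = int(round(cfg.control_interval / cfg.dt))
    controls_per_frame = int(round(cfg.frame_interval / cfg.control_interval))
    n_controls = int(round(cfg.duration / cfg.control_interval))

    refr_mask = None
    if cfg.barrier is not None and cfg.barrier.mode == "refractory":
        refr_mask = barrier_lattice_mask(cfg.ny, cfg.nx, cfg.barrier.block,
                                         cfg.barrier.thickness)
    barrier_applied = False

    frames_t = [ts.time]
    frames_v = [ts.V.astype(np.float32)]
    frames_na = [ts.na_availability().astype(np.float32)] if cfg.record_gates else None
    frames_ca = [ts.ca_gate_openness().astype(np.float32)] if cfg.record_gates else None

    run_log = {"aborted": False, "events": [], "wall_start": _time.time()}
    it = range(n_controls)
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(it, desc="tissue run")
        except ImportError:
            pass
    try:
        for k in it:
            t = ts.time
            if (cfg.barrier is not None and not barrier_applied
                    and t >= cfg.barrier.start_time):
                if cfg.barrier.mode == "mask":
                    apply_barrier_grid(ts, cfg.barrier.block,
                                       cfg.barrier.thickness)
                barrier_applied = True
                run_log["events"].append({"t": float(t),
                                          "event": "barrier_applied"})
            proto.check(ts, t, cfg)
            stim = proto.stim_field(ts, t, cfg)
            if refr_mask is not None and barrier_applied:
                if stim is None:
                    stim = np.zeros((cfg.ny, cfg.nx))
                stim = stim.copy()
                stim[refr_mask] = cfg.barrier.refractory_amplitude
            step_tissue(ts, cfg, i_stim=stim, n_steps=steps_per_control,
                        params=p)
            if (k + 1) % controls_per_frame == 0:
                frames_t.append(ts.time)
                frames_v.append(ts.V.astype(np.float32))
                if cfg.record_gates:
                    frames_na.append(ts.na_availability().astype(np.float32))
                    frames_ca.append(ts.ca_gate_openness().astype(np.float32))
    except _kernels.IntegrationError as err:
        run_log["aborted"] = True
        run_log["error"] = str(err)
        log.error("run aborted: %s", err)

    run_log["events"].extend(proto.events())
    run_log["wall_seconds"] = _time.time() - run_log.pop("wall_start")
    frames = FrameSeries(
        times=np.asarray(frames_t), V=np.stack(frames_v),
        na=np.stack(frames_na) if cfg.record_gates else None,
        ca=np.stack(frames_ca) if cfg.record_gates else None,
        dx=cfg.dx,
        meta={"config": cfg.to_dict(), "dt": cfg.dt,
              "multipliers": [cfg.mult_CaL, cfg.mult_Ks, cfg.mult_Kr,
                              cfg.mult_NaCa]},
        stim_log=run_log["events"])
    return RunResult(frames=frames, state=ts, log=run_log, config=cfg)
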