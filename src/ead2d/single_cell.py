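"""Single-cell action potentials: simulation, EAD classification, sweeps.

An early afterdepolarization (EAD) is a depolarizing reversal of the
membrane voltage during the repolarizing phase, before the cell returns
to rest.  The classifier below implements that definition with three
explicit thresholds (see :class:`ClassifierConfig`): a local minimum of
V followed by a rise of at least ``rise_min`` while V is still above
``plateau_floor`` counts as an EAD; a trace that never drops below
``rest_threshold`` within ``window_rest`` after the last stimulus is
oscillatory (non-repolarization dominates any EAD count).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from . import _kernels
from .ionic_model import (N_STATE, CellState, ModelParams, compute_currents,
                          find_rest_state, make_params)

__all__ = [
    "APTrace", "APClassification", "PhaseDiagram", "ClassifierConfig",
    "StimulusConfig", "simulate_ap", "classify_ap", "detect_ead_drivers",
    "sweep_phase_diagram",
]

log = logging.getLogger(__name__)

LABEL_NORMAL = "NORMAL"
LABEL_EAD = "EAD"
LABEL_OSC = "OSCILLATORY"
LABEL_FAILED = "FAILED"

Y_CHANNELS = {"Ks": "mult_Ks", "Kr": "mult_Kr", "NaCa": "mult_NaCa"}


@dataclass(frozen=True)
class StimulusConfig:
    """Single-cell stimulus: 20 pA/pF for 2 ms (configurable)."""

    amplitude: float = 20.0   # pA/pF, depolarizing-positive
    duration: float = 2.0     # ms


@dataclass(frozen=True)
class ClassifierConfig:
    rise_min: float = 1.0          # mV rise after a local minimum
    plateau_floor: float = -40.0   # EADs only count above this voltage
    ead_ceiling: float = 20.0      # ... and below this one (excludes the
    #                                normal spike-notch-dome morphology)
    rest_threshold: float = -75.0  # "returned to rest" level
    window_rest: float = 3000.0    # ms after last stimulus


@dataclass
class APTrace:
    """Uniformly sampled voltage trace with its stimulus schedule."""

    t: np.ndarray                    # ms
    V: np.ndarray                    # mV
    currents: Optional[dict] = None  # name -> array [pA/pF]
    stim_onsets: tuple = ()
    stim_amplitude: float = 0.0
    stim_duration: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.shape != self.V.shape:
            raise ValueError("t and V must have equal length")
        dts = np.diff(self.t)
        if self.t.size > 1 and (np.any(dts <= 0)
                                or not np.allclose(dts, dts[0], rtol=1e-9)):
            raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self):
        import pandas as pd
        d = {"t": self.t, "V": self.V}
        if self.currents:
            d.update(self.currents)
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class APClassification:
    label: str
    ead_count: int
    returned_to_rest: bool
    ead_times: list

    def __post_init__(self):
        if self.label == LABEL_NORMAL:
            assert self.ead_count == 0 and self.returned_to_rest
        if self.label == LABEL_EAD:
            assert self.ead_count >= 1 and self.returned_to_rest
        if self.label == LABEL_OSC:
            assert not self.returned_to_rest


_rest_cache: dict = {}


def _rest_vector(p: ModelParams) -> np.ndarray:
    v = _rest_cache.get(p)
    if v is None:
        v = find_rest_state(p).to_vector()
        if len(_rest_cache) > 512:
            _rest_cache.clear()
        _rest_cache[p] = v
    return v.copy()


def simulate_ap(p: ModelParams, n_beats: int = 1, cycle_length: float = 1000.0,
                record_currents: bool = False, *,
                stim: StimulusConfig = StimulusConfig(),
                tail_ms: float = 4000.0, dt: float = 0.02,
                sample_ms: float = 1.0,
                initial_state: Optional[CellState] = None,
                euler_gates: bool = False) -> APTrace:
    """Pace a cell ``n_beats`` times at ``cycle_length`` and record V.

    The cell starts from its quiescent steady state (found once per
    parameter set and cached).  Output is sampled every ``sample_ms``
    while integrating at ``dt``.  ``tail_ms`` of free run is appended
    after the last stimulus so the classifier window is covered.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if cycle_length < 300.0:
        raise ValueError("cycle_length must be >= 300 ms")
    steps_per_sample = int(round(sample_ms / dt))
    if abs(steps_per_sample * dt - sample_ms) > 1e-9:
        raise ValueError("sample_ms must be a multiple of dt")

    vec = (initial_state.to_vector() if initial_state is not None
           else _rest_vector(p))
    S = vec.reshape(1, N_STATE)

    onsets = tuple(i * cycle_length for i in range(n_beats))
    duration = onsets[-1] + tail_ms
    n_samples = int(round(duration / sample_ms))

    t = np.arange(n_samples + 1) * sample_ms
    V = np.empty(n_samples + 1)
    V[0] = S[0, 0]
    cur_names = list(compute_currents(CellState.from_vector(S[0]), p).as_dict())
    currents = ({k: np.empty(n_samples + 1) for k in cur_names}
                if record_currents else None)
    if record_currents:
        for k, v in compute_currents(CellState.from_vector(S[0]), p).as_dict().items():
            currents[k][0] = v

    stim_arr = np.zeros(1)
    for i in range(n_samples):
        t0 = i * sample_ms
        # stimulus level for this sample window (schedule is on the
        # sample grid; sub-sample onsets are not supported)
        level = 0.0
        for on in onsets:
            if on <= t0 < on + stim.duration:
                level = stim.amplitude
                break
        stim_arr[0] = level
        _kernels.advance(S, p, dt, steps_per_sample, stim_arr,
                         euler_gates=euler_gates)
        V[i + 1] = S[0, 0]
        if record_currents:
            cs = compute_currents(CellState.from_vector(S[0]), p)
            for k, v in cs.as_dict().items():
                currents[k][i + 1] = v

    return APTrace(t=t, V=V, currents=currents, stim_onsets=onsets,
                   stim_amplitude=stim.amplitude, stim_duration=stim.duration,
                   meta={"dt": dt, "params": p.to_dict(),
                         "final_state": S[0].tolist()})


class InsufficientDataError(ValueError):
    pass


def classify_ap(tr: APTrace,
                cfg: ClassifierConfig = ClassifierConfig()) -> APClassification:
    """Label a trace NORMAL / EAD / OSCILLATORY.

    Deterministic: identical traces yield identical classifications.
    """
    last_on = tr.stim_onsets[-1] if tr.stim_onsets else tr.t[0]
    t_end = tr.t[-1]
    if t_end - last_on < cfg.window_rest:
        raise InsufficientDataError(
            f"trace covers only {t_end - last_on:.0f} ms after the last "
            f"stimulus; classifier needs {cfg.window_rest:.0f} ms")

    i_on = int(np.searchsorted(tr.t, last_on))
    seg_v = tr.V[i_on:]
    seg_t = tr.t[i_on:]

    # upstroke = sample right after the steepest rise following the stimulus
    i_up = int(np.argmax(np.diff(seg_v[: max(10, int(200 / tr.dt))]))) + 1 \
        if seg_v.size > 2 else 0

    in_window = seg_t - last_on <= cfg.window_rest
    returned = bool(np.any(seg_v[in_window][i_up:] < cfg.rest_threshold))

    # repolarization segment: upstroke -> first return below rest level
    below = np.flatnonzero(seg_v[i_up:] < cfg.rest_threshold)
    i_end = i_up + int(below[0]) + 1 if below.size else seg_v.size
    rep = seg_v[i_up:i_end]
    rep_t = seg_t[i_up:i_end]

    ead_times = []
    if rep.size >= 3:
        minima, _ = find_peaks(-rep)
        maxima, _ = find_peaks(rep)
        if rep[-1] > rep[-2]:          # rising at segment end
            maxima = np.append(maxima, rep.size - 1)
        for mi in minima:
            if rep[mi] <= cfg.plateau_floor or rep[mi] >= cfg.ead_ceiling:
                continue
            nxt = maxima[maxima > mi]
            if nxt.size and rep[nxt[0]] - rep[mi] >= cfg.rise_min:
                ead_times.append(float(rep_t[mi]))

    if not returned:
        label = LABEL_OSC
    elif ead_times:
        label = LABEL_EAD
    else:
        label = LABEL_NORMAL
    return APClassification(label=label, ead_count=len(ead_times),
                            returned_to_rest=returned, ead_times=ead_times)


@dataclass
class EADOnset:
    """Current balance at one EAD onset (the dV/dt zero crossing)."""

    time: float
    currents: dict                 # name -> pA/pF at onset
    dominant_inward: Optional[str]
    i_cal_dominant: bool


def detect_ead_drivers(tr: APTrace,
                       cfg: ClassifierConfig = ClassifierConfig()) -> list:
    """Per-EAD inward/outward current balance at onset.

    Requires a trace recorded with ``record_currents=True``.  The main
    driver of an EAD in this model is reactivation of I_CaL; the report
    flags whether I_CaL is the largest inward (most negative) term at
    each onset.  Returns an empty list when the trace has no EADs.
    """
    if tr.currents is None:
        raise ValueError("trace was recorded without currents")
    cls = classify_ap(tr, cfg)
    out = []
    for t_onset in cls.ead_times:
        idx = int(np.argmin(np.abs(tr.t - t_onset)))
        vals = {k: float(v[idx]) for k, v in tr.currents.items()
                if k != "i_ion"}
        inward = {k: v for k, v in vals.items() if v < 0}
        dom = min(inward, key=inward.get) if inward else None
        out.append(EADOnset(time=float(t_onset), currents=vals,
                            dominant_inward=dom,
                            i_cal_dominant=(dom == "i_CaL")))
    return out


@dataclass
class PhaseDiagram:
    """Grid of AP labels over (G_CaL multiplier) x (one K/NaCa multiplier)."""

    x_mults: np.ndarray            # G_CaL multipliers
    y_channel: str                 # "Ks" | "Kr" | "NaCa"
    y_mults: np.ndarray
    labels: np.ndarray             # (len(x), len(y)) of str
    ead_counts: np.ndarray         # (len(x), len(y)) of int
    meta: dict = field(default_factory=dict)

    _ORDER = {LABEL_NORMAL: 0, LABEL_EAD: 1, LABEL_OSC: 2}

    def ordering_violations(self) -> list:
        """Grid points where increasing G_CaL at fixed y reverses the
        NORMAL -> EAD -> OSCILLATORY progression."""
        bad = []
        for iy in range(len(self.y_mults)):
            prev = -1
            for ix in range(len(self.x_mults)):
                lab = self.labels[ix, iy]
                if lab == LABEL_FAILED:
                    continue
                rank = self._ORDER[lab]
                if rank < prev:
                    bad.append((float(self.x_mults[ix]),
                                float(self.y_mults[iy]), lab))
                prev = max(prev, rank)
        return bad

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.labels.T,
                          index=[f"{y:g}" for y in self.y_mults],
                          columns=[f"{x:g}" for x in self.x_mults])
        df.index.name = f"mult_{self.y_channel}\\mult_CaL"
        df.to_csv(path)

    def to_json_meta(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"x_mults": list(map(float, self.x_mults)),
                       "y_channel": self.y_channel,
                       "y_mults": list(map(float, self.y_mults)),
                       **self.meta}, fh, indent=1)


def sweep_phase_diagram(x_mults: Sequence[float], y_channel: str,
                        y_mults: Sequence[float], *,
                        cls_cfg: ClassifierConfig = ClassifierConfig(),
                        stim: StimulusConfig = StimulusConfig(),
                        n_beats: int = 1, cycle_length: float = 1000.0,
                        tail_ms: Optional[float] = None, dt: float = 0.02,
                        tau_f_scale: float = 0.5,
                        progress: bool = False) -> PhaseDiagram:
    """Classify every (mult_CaL, mult_y) grid point independently.

    Failed integrations are marked ``FAILED`` and logged; the sweep
    continues.  The sweep is deterministic and embarrassingly parallel
    (each point is an independent simulation from a quiescent start).
    """
    if y_channel not in Y_CHANNELS:
        raise ValueError(f"y_channel must be one of {sorted(Y_CHANNELS)}")
    x_mults = np.asarray(list(x_mults), dtype=float)
    y_mults = np.asarray(list(y_mults), dtype=float)
    if x_mults.size == 0 or y_mults.size == 0:
        raise ValueError("sweep axes must be non-empty")
    if np.any(np.diff(x_mults) <= 0) or np.any(np.diff(y_mults) <= 0):
        raise ValueError("sweep axes must be sorted ascending")
    if tail_ms is None:
        tail_ms = cls_cfg.window_rest + 1000.0

    labels = np.full((x_mults.size, y_mults.size), LABEL_FAILED, dtype=object)
    counts = np.zeros((x_mults.size, y_mults.size), dtype=int)
    it = [(ix, iy) for ix in range(x_mults.size) for iy in range(y_mults.size)]
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(it, desc="cell sweep")
        except ImportError:
            pass
    for ix, iy in it:
        kw = {Y_CHANNELS[y_channel]: float(y_mults[iy])}
        p = make_params(mult_CaL=float(x_mults[ix]),
                        tau_f_scale=tau_f_scale, **kw)
        try:
            tr = simulate_ap(p, n_beats=n_beats, cycle_length=cycle_length,
                             stim=stim, tail_ms=tail_ms, dt=dt)
            cls = classify_ap(tr, cls_cfg)
        except Exception:
            log.exception("sweep point (mult_CaL=%g, mult_%s=%g) failed",
                          x_mults[ix], y_channel, y_mults[iy])
            continue
        labels[ix, iy] = cls.label
        counts[ix, iy] = cls.ead_count
    return PhaseDiagram(x_mults=x_mults, y_channel=y_channel, y_mults=y_mults,
                        labels=labels, ead_counts=counts,
                        meta={"n_beats": n_beats, "cycle_length": cycle_length,
                              "tau_f_scale": tau_f_scale, "dt": dt})
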