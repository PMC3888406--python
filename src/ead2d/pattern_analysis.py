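"""Classification of emergent 2D patterns and their electrophysiological
signatures.

The study distinguishes, for sustained activity:

* **SF_a** - spiral fibrillation maintained by small-amplitude,
  L-type-Ca-mediated waves (cells never repolarize far enough to recover
  I_Na);
* **SF_b** - spiral fibrillation in which a substantial fraction of
  wavefronts are Na-mediated (full-amplitude waves from well-repolarized
  tissue);
* **Osc** - synchronized small-amplitude oscillations whose apparent
  propagation is a phase wave (unblocked by non-conducting barriers).

Wave attribution inspects each upstroke's pre-upstroke voltage floor and
the sodium availability m^3 h j at the front: sodium can only carry the
upstroke if the cell repolarized below ``na_floor`` and the h/j gates
recovered.  The SF_a / SF_b boundary is gradual, so the continuous
``na_fraction`` is always reported alongside the discrete label.

Pseudo-ECG: a far-field electrode at height 2.5 mm above the domain
centre, ECG(t) = sum over nodes of grad V . grad(1/r) dA.

Spectra: per-node mean-removed periodograms summed over an even
sublattice of (by default) 10000 points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .tissue2d import FrameSeries, RunResult

__all__ = [
    "AnalysisConfig", "WaveAttribution", "Spectrum", "ECGTrace",
    "PatternReport", "pseudo_ecg", "mean_power_spectrum", "attribute_waves",
    "interbeat_intervals", "sustained_activity", "classify_pattern",
    "classify_run", "phase_wave_test", "barrier_verdict", "line_profile",
    "count_phase_singularities", "phase_map",
]

log = logging.getLogger(__name__)

LABEL_SFA = "SF_a"
LABEL_SFB = "SF_b"
LABEL_OSC = "OSC"
LABEL_SELF_TERM = "SELF_TERMINATED_SFa"
LABEL_NO_SUST = "NO_SUSTAINED_EAD"
LABEL_PLAIN = "PLAIN_PROPAGATION"
LABEL_SINGLE = "SINGLE_SPIRAL"
LABEL_UNCLASSIFIED = "UNCLASSIFIED"

TRIGGER_WAVES = "TRIGGER_WAVES"
PHASE_WAVES = "PHASE_WAVES"


class ResolutionError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the pattern classifiers (all config-exposed; the
    discriminations are qualitative in nature and gradual at the
    boundaries)."""

    v_thresh: float = -30.0        # upstroke threshold [mV]
    na_floor: float = -60.0        # I_Na recovers only below this floor
    na_avail_min: float = 0.01     # minimal m^3 h j for a Na-led front
    sf_split: float = 0.2          # na_fraction boundary SF_a | SF_b
    osc_amp_max: float = 40.0      # per-node amplitude bound for Osc [mV]
    v_active: float = -70.0        # "electrically active" level [mV]
    # EAD detection on node traces; the rise threshold is higher than in
    # the single-cell classifier because tissue traces near spiral cores
    # carry small electrotonic bumps that are not regenerative EADs
    rise_min: float = 10.0
    plateau_floor: float = -40.0
    ead_ceiling: float = 20.0
    rest_threshold: float = -75.0
    # sustainment window: 3 s after the last stimulus plus one domain
    # crossing at a conservative conduction speed
    sustain_window_ms: float = 3000.0
    crossing_speed: float = 0.3    # mm/ms
    dev_delay_ms: float = 500.0    # developed-state window starts this
    #                                long after the last stimulus
    # spectra
    spectrum_points: int = 10000
    min_spectrum_ms: float = 4000.0
    peak_factor: float = 5.0       # peak must exceed this x median power
    # phase / spiral analysis (time-delay phase embedding)
    tau_ms: float = 50.0
    ps_stride_ms: float = 50.0
    # barrier verdict
    amp_active_min: float = 5.0    # mV; node counts as active
    die_fraction: float = 0.1
    phase_ratio_max: float = 3.0
    # a cross-barrier phase step below this is continuous regardless of
    # the interior gradient (a near-uniform oscillation has interior
    # steps ~0, which would make any ratio test explode)
    phase_jump_max: float = 0.5    # rad
    n_ead_nodes: int = 64
    max_attr_nodes: int = 2500


# ---------------------------------------------------------------------------
# pseudo-ECG
# ---------------------------------------------------------------------------

@dataclass
class ECGTrace:
    t: np.ndarray
    ecg: np.ndarray
    electrode: tuple

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"t": self.t, "ecg": self.ecg}).to_csv(path, index=False)


def pseudo_ecg(frames: FrameSeries,
               electrode: Optional[tuple] = None) -> ECGTrace:
    """Far-field potential proxy: ECG(t) = sum grad V . grad(1/r) dA.

    Node (y, x) sits at (x*dx, y*dx, 0) mm; the default electrode is
    2.5 mm above the domain centre.  grad V is the 2D central-difference
    gradient; r is the node-to-electrode distance.
    """
    ny, nx, dx = frames.ny, frames.nx, frames.dx
    if electrode is None:
        electrode = ((nx - 1) * dx / 2.0, (ny - 1) * dx / 2.0, 2.5)
    ex, ey, ez = map(float, electrode)

    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dx
    X, Y = np.meshgrid(xs, ys)
    r = np.sqrt((X - ex) ** 2 + (Y - ey) ** 2 + ez ** 2)
    if np.any(r < 1e-9):
        raise ZeroDivisionError(
            "electrode coincides with a tissue node (1/r singularity)")
    # grad of 1/r with respect to the node position
    wx = -(X - ex) / r ** 3
    wy = -(Y - ey) / r ** 3

    V = frames.V.astype(float)
    gy, gx = np.gradient(V, dx, dx, axis=(1, 2))
    ecg = (gx * wx + gy * wy).sum(axis=(1, 2)) * dx ** 2
    return ECGTrace(t=frames.times.copy(), ecg=ecg, electrode=(ex, ey, ez))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    freq: np.ndarray            # Hz
    power: np.ndarray           # summed power density (arbitrary units)
    n_points: int               # nodes actually summed
    sampling_interval: float    # ms
    peaks: list                 # (frequency, power), sorted by power desc

    @property
    def dominant_frequency(self) -> float:
        """Frequency of the absolute power maximum (DC excluded)."""
        i = int(np.argmax(self.power[1:])) + 1
        return float(self.freq[i])

    @property
    def bin_width(self) -> float:
        return float(self.freq[1] - self.freq[0])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"freq_hz": self.freq, "power": self.power}).to_csv(
            path, index=False)


def _sublattice(ny: int, nx: int, n_points: int, offset: int = 0):
    stride = max(1, int(np.floor(np.sqrt(ny * nx / n_points))))
    yy = np.arange(offset % stride, ny, stride)
    xx = np.arange(offset % stride, nx, stride)
    return yy, xx


def mean_power_spectrum(frames: FrameSeries, n_points: int = 10000, *,
                        offset: int = 0, window: Optional[str] = None,
                        min_duration_ms: float = 4000.0,
                        peak_factor: float = 5.0,
                        t_start: float = 0.0) -> Spectrum:
    """Summed temporal power spectrum of V over an even sublattice.

    Each sampled node contributes its mean-removed periodogram; the sum
    characterizes the whole pattern.  ``offset`` shifts the sublattice
    (peak frequencies of stationary signals are invariant under it).
    """
    sel = frames.times >= t_start
    t = frames.times[sel]
    duration = t[-1] - t[0] if t.size > 1 else 0.0
    if duration < min_duration_ms:
        raise ResolutionError(
            f"record of {duration:.0f} ms gives only "
            f"{1000.0 / max(duration, 1e-9):.3f} Hz resolution; need "
            f">= {min_duration_ms:.0f} ms")
    dt_ms = float(t[1] - t[0])
    yy, xx = _sublattice(frames.ny, frames.nx, n_points, offset)
    sig = frames.V[np.ix_(sel, yy, xx)].reshape(t.size, -1).astype(float)
    sig -= sig.mean(axis=0, keepdims=True)
    if window == "hann":
        sig *= np.hanning(t.size)[:, None]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    F = np.fft.rfft(sig, axis=0)
    power = (np.abs(F) ** 2).sum(axis=1)
    freq = np.fft.rfftfreq(t.size, d=dt_ms / 1000.0)

    med = np.median(power[1:])
    # a peak must beat the median noise floor by peak_factor and carry a
    # non-negligible fraction of the strongest line
    floor = max(peak_factor * med, 1e-4 * power[1:].max())
    idx, _ = find_peaks(power, height=floor)
    idx = idx[idx > 0]
    order = np.argsort(power[idx])[::-1]
    peaks = [(float(freq[i]), float(power[i])) for i in idx[order]]
    return Spectrum(freq=freq, power=power, n_points=sig.shape[1],
                    sampling_interval=dt_ms, peaks=peaks)


# ---------------------------------------------------------------------------
# upstroke detection, wave attribution, interbeat intervals
# ---------------------------------------------------------------------------

def _upstroke_indices(v: np.ndarray, thresh: float) -> np.ndarray:
    return np.flatnonzero((v[:-1] < thresh) & (v[1:] >= thresh)) + 1


@dataclass
class WaveAttribution:
    """Na- vs Ca-mediated upstroke bookkeeping."""

    records: list               # dicts: node, time, floor, na_avail, label
    na_fraction: float
    ca_fraction: float
    n_upstrokes: int


def attribute_waves(frames: FrameSeries,
                    cfg: AnalysisConfig = AnalysisConfig(), *,
                    t_start: float = 0.0) -> WaveAttribution:
    """Label every sampled upstroke Na- or Ca-mediated.

    An upstroke (upward crossing of ``v_thresh``) is Na-mediated when
    the voltage floor since the previous beat is below ``na_floor`` and
    the sodium availability m^3 h j at the crossing frame exceeds
    ``na_avail_min``; otherwise the L-type Ca current carried it.
    """
    if frames.na is None:
        raise ValueError("frames lack the Na gate-product channel")
    yy, xx = _sublattice(frames.ny, frames.nx, cfg.max_attr_nodes)
    sel = frames.times >= t_start
    t = frames.times[sel]
    V = frames.V[np.ix_(sel, yy, xx)].reshape(t.size, -1)
    NA = frames.na[np.ix_(sel, yy, xx)].reshape(t.size, -1)
    CA = (frames.ca[np.ix_(sel, yy, xx)].reshape(t.size, -1)
          if frames.ca is not None else None)

    records = []
    n_na = 0
    for k in range(V.shape[1]):
        v = V[:, k]
        ups = _upstroke_indices(v, cfg.v_thresh)
        downs = np.flatnonzero((v[:-1] >= cfg.v_thresh) & (v[1:] < cfg.v_thresh)) + 1
        for ui in ups:
            prev = downs[downs < ui]
            lo = int(prev[-1]) if prev.size else 0
            floor = float(v[lo:ui].min())
            na_av = float(NA[ui - 1, k])
            is_na = floor < cfg.na_floor and na_av > cfg.na_avail_min
            n_na += is_na
            records.append({
                "node": (int(yy[k // xx.size]), int(xx[k % xx.size])),
                "time": float(t[ui]), "floor": floor, "na_avail": na_av,
                "ca_open": float(CA[ui - 1, k]) if CA is not None else None,
                "label": "na" if is_na else "ca"})
    n = len(records)
    na_f = n_na / n if n else 0.0
    ca_f = (n - n_na) / n if n else 0.0
    return WaveAttribution(records=records, na_fraction=na_f,
                           ca_fraction=ca_f, n_upstrokes=n)


@dataclass
class IntervalReport:
    per_node: list            # (node, intervals[ms], amplitudes[mV])
    histogram: np.ndarray     # interval x amplitude-band counts
    interval_edges: np.ndarray
    amplitude_edges: np.ndarray


def interbeat_intervals(frames: FrameSeries,
                        nodes: Optional[Sequence[tuple]] = None,
                        cfg: AnalysisConfig = AnalysisConfig(), *,
                        t_start: float = 0.0,
                        interval_bins=None, amplitude_bins=None) -> IntervalReport:
    """Intervals between successive upstrokes with per-beat amplitude.

    A beat's amplitude is max-min of V between its bounding upstrokes,
    so small Ca-waves and full-amplitude Na-waves form separate
    interval/amplitude clusters.
    """
    if nodes is None:
        yy, xx = _sublattice(frames.ny, frames.nx, cfg.max_attr_nodes)
        nodes = [(int(y), int(x)) for y in yy for x in xx]
    sel = frames.times >= t_start
    t = frames.times[sel]
    per_node = []
    all_iv, all_amp = [], []
    for (y, x) in nodes:
        v = frames.V[sel, y, x].astype(float)
        ups = _upstroke_indices(v, cfg.v_thresh)
        ivs, amps = [], []
        for a, b in zip(ups[:-1], ups[1:]):
            ivs.append(float(t[b] - t[a]))
            amps.append(float(v[a:b + 1].max() - v[a:b + 1].min()))
        per_node.append(((y, x), ivs, amps))
        all_iv.extend(ivs)
        all_amp.extend(amps)
    if interval_bins is None:
        interval_bins = np.linspace(0.0, 1000.0, 51)
    if amplitude_bins is None:
        amplitude_bins = np.linspace(0.0, 140.0, 15)
    H, ie, ae = np.histogram2d(all_iv, all_amp,
                               bins=[interval_bins, amplitude_bins])
    return IntervalReport(per_node=per_node, histogram=H,
                          interval_edges=ie, amplitude_edges=ae)


def sustained_activity(frames: FrameSeries, t_after_last_stim: float,
                       v_active: float = -70.0) -> bool:
    """True iff any node is still above ``v_active`` beyond the given
    absolute time (ms)."""
    if t_after_last_stim > frames.times[-1]:
        raise ValueError(
            f"record ends at {frames.times[-1]:.0f} ms, before the "
            f"sustainment check time {t_after_last_stim:.0f} ms")
    sel = frames.times >= t_after_last_stim
    return bool((frames.V[sel] > v_active).any())


def line_profile(frames: FrameSeries, row: Optional[int] = None,
                 col: Optional[int] = None) -> np.ndarray:
    """Space-time voltage matrix (nt, n) along one row or column."""
    if (row is None) == (col is None):
        raise ValueError("give exactly one of row / col")
    if row is not None:
        if not 0 <= row < frames.ny:
            raise IndexError(f"row {row} outside 0..{frames.ny - 1}")
        return frames.V[:, row, :].astype(float)
    if not 0 <= col < frames.nx:
        raise IndexError(f"col {col} outside 0..{frames.nx - 1}")
    return frames.V[:, :, col].astype(float)


# ---------------------------------------------------------------------------
# phase analysis: time-delay embedding, singularity counting
# ---------------------------------------------------------------------------

def _midrange(frames: FrameSeries) -> np.ndarray:
    """Per-node embedding reference: midpoint of the voltage excursion
    (centres the (V(t), V(t-tau)) orbit for pulse-like signals)."""
    return (frames.V.max(axis=0).astype(float)
            + frames.V.min(axis=0).astype(float)) / 2.0


def phase_map(frames: FrameSeries, t_index: int, tau_frames: int,
              v_star: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-node phase at one frame via time-delay embedding:
    angle of (V(t) - V*, V(t - tau) - V*)."""
    if t_index < tau_frames:
        raise ValueError("t_index must leave room for the delay")
    if v_star is None:
        v_star = _midrange(frames)
    a = frames.V[t_index].astype(float) - v_star
    b = frames.V[t_index - tau_frames].astype(float) - v_star
    return np.arctan2(b, a)


def _winding(phase: np.ndarray) -> np.ndarray:
    """Topological charge of every 2x2 plaquette (line integral of the
    wrapped phase gradient)."""
    def wrap(d):
        return (d + np.pi) % (2.0 * np.pi) - np.pi
    d1 = wrap(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = wrap(phase[1:, 1:] - phase[:-1, 1:])
    d3 = wrap(phase[1:, :-1] - phase[1:, 1:])
    d4 = wrap(phase[:-1, :-1] - phase[1:, :-1])
    return np.rint((d1 + d2 + d3 + d4) / (2.0 * np.pi)).astype(int)


def count_phase_singularities(frames: FrameSeries, t_index: int,
                              tau_frames: int,
                              v_star: Optional[np.ndarray] = None,
                              min_amplitude: float = 20.0) -> int:
    """Number of phase singularities (spiral tips) at one frame.

    Plaquettes whose four corners all have sub-threshold temporal
    amplitude are ignored (phase is undefined in quiescent tissue).
    """
    ph = phase_map(frames, t_index, tau_frames, v_star)
    w = _winding(ph)
    # amplitude mask local in time: quiescent-by-then tissue is excluded
    lo = max(0, t_index - 3 * tau_frames)
    Vw = frames.V[lo:t_index + 1]
    amp = Vw.max(axis=0) - Vw.min(axis=0)
    quiet = amp < min_amplitude
    live = ~(quiet[:-1, :-1] & quiet[:-1, 1:] & quiet[1:, :-1] & quiet[1:, 1:])
    return int(np.count_nonzero(w * live))


def _ps_series(frames: FrameSeries, cfg: AnalysisConfig, t_start: float):
    dt = frames.frame_interval
    if dt <= 0:
        return []
    tau = max(1, int(round(cfg.tau_ms / dt)))
    stride = max(1, int(round(cfg.ps_stride_ms / dt)))
    v_star = _midrange(frames)
    first = max(tau, int(np.searchsorted(frames.times, t_start)))
    out = []
    for k in range(first, frames.times.size, stride):
        out.append((float(frames.times[k]),
                    count_phase_singularities(frames, k, tau, v_star)))
    return out


# ---------------------------------------------------------------------------
# EAD detection on node traces
# ---------------------------------------------------------------------------

def _trace_has_ead(v: np.ndarray, cfg: AnalysisConfig) -> bool:
    if v.size < 3:
        return False
    minima, _ = find_peaks(-v)
    maxima, _ = find_peaks(v)
    if v.size >= 2 and v[-1] > v[-2]:
        maxima = np.append(maxima, v.size - 1)
    for mi in minima:
        if not (cfg.plateau_floor < v[mi] < cfg.ead_ceiling):
            continue
        nxt = maxima[maxima > mi]
        if nxt.size and v[nxt[0]] - v[mi] >= cfg.rise_min:
            # reversal during repolarization, i.e. before the trace has
            # returned to rest since the preceding upstroke
            prev = v[:mi]
            since_up = prev[prev >= cfg.v_thresh]
            if since_up.size and not np.any(
                    prev[np.argmax(prev >= cfg.v_thresh):mi]
                    < cfg.rest_threshold):
                return True
    return False


def _eads_anywhere(frames: FrameSeries, cfg: AnalysisConfig,
                   t_start: float = 0.0) -> bool:
    yy, xx = _sublattice(frames.ny, frames.nx, cfg.n_ead_nodes)
    sel = frames.times >= t_start
    for y in yy:
        for x in xx:
            if _trace_has_ead(frames.V[sel, y, x].astype(float), cfg):
                return True
    return False


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

@dataclass
class PatternReport:
    label: str
    sustained: bool
    na_fraction: float
    ca_fraction: float
    n_upstrokes: int
    dominant_frequencies: list
    amplitude_median: float
    amplitude_p95: float
    min_v_statistics: dict
    ps_counts: list               # (t, count)
    ead_present: bool
    breaks_occurred: bool
    evidence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json
        d = dict(self.__dict__)
        d["ps_counts"] = [[t, c] for t, c in self.ps_counts]
        return json.dumps(d, indent=1, default=float)


def classify_pattern(frames: FrameSeries, *, last_stim: float = 0.0,
                     protocol: Optional[str] = None,
                     cfg: AnalysisConfig = AnalysisConfig(),
                     phase_verdict: Optional[str] = None,
                     compute_spectrum: bool = True) -> PatternReport:
    """Assign one of the pattern labels from the evidence.

    Decision rules (thresholds from ``cfg``):

    * not sustained -> PLAIN_PROPAGATION (no EADs anywhere),
      NO_SUSTAINED_EAD (EADs occurred), or SELF_TERMINATED_SFa (wave
      breakup occurred, then the activity died);
    * sustained -> SINGLE_SPIRAL (exactly one persistent rotating front,
      no EAD breaks); OSC (no Na-led upstrokes, small per-node
      amplitude, and - when available - a phase-wave verdict); else
      SF_a when ``na_fraction < sf_split`` and SF_b otherwise.

    Conflicting evidence yields UNCLASSIFIED with the evidence attached.
    """
    if protocol is None:
        protocol = frames.meta.get("config", {}).get("protocol", "p1")

    t_end = float(frames.times[-1])
    crossing = frames.nx * frames.dx / cfg.crossing_speed
    t_check = last_stim + cfg.sustain_window_ms + crossing
    sustained = sustained_activity(frames, t_check, cfg.v_active)

    t_dev = last_stim + cfg.dev_delay_ms
    attr = (attribute_waves(frames, cfg, t_start=t_dev)
            if frames.na is not None else
            WaveAttribution([], 0.0, 0.0, 0))

    sel_dev = frames.times >= t_dev
    Vdev = frames.V[sel_dev]
    amp = (Vdev.max(axis=0) - Vdev.min(axis=0)).astype(float)
    amp_med = float(np.median(amp))
    amp_p95 = float(np.percentile(amp, 95))
    vmin = Vdev.min(axis=0).astype(float)

    ead = _eads_anywhere(frames, cfg, t_start=last_stim)
    ps = _ps_series(frames, cfg, t_start=last_stim)
    counts = [c for _, c in ps]
    ps_max = max(counts) if counts else 0
    break_bar = 2 if protocol == "p2" else 1
    # a break must persist over at least two phase samples
    breaks = sum(1 for c in counts if c >= break_bar) >= 2

    tail = [c for _, c in ps[len(ps) // 2:]]
    ps_tail_median = float(np.median(tail)) if tail else 0.0

    freqs = []
    spectrum = None
    if compute_spectrum:
        try:
            spectrum = mean_power_spectrum(
                frames, cfg.spectrum_points, t_start=t_dev,
                min_duration_ms=cfg.min_spectrum_ms,
                peak_factor=cfg.peak_factor)
            freqs = [f for f, _ in spectrum.peaks[:5]]
            if not freqs:
                freqs = [spectrum.dominant_frequency]
        except ResolutionError:
            pass

    label = LABEL_UNCLASSIFIED
    if not sustained:
        if breaks:
            label = LABEL_SELF_TERM
        elif ead:
            label = LABEL_NO_SUST
        else:
            label = LABEL_PLAIN
    else:
        osc_ok = (attr.na_fraction == 0.0 and amp_p95 < cfg.osc_amp_max
                  and phase_verdict in (None, PHASE_WAVES))
        single_ok = (ps_tail_median == 1.0 and not ead)
        if single_ok and not osc_ok:
            label = LABEL_SINGLE
        elif osc_ok and not single_ok:
            label = LABEL_OSC
        elif osc_ok and single_ok:
            label = LABEL_UNCLASSIFIED
        elif attr.n_upstrokes == 0:
            # sustained, large-amplitude, yet no upstrokes sampled
            label = LABEL_UNCLASSIFIED
        elif attr.na_fraction < cfg.sf_split:
            label = LABEL_SFA
        else:
            label = LABEL_SFB

    return PatternReport(
        label=label, sustained=sustained,
        na_fraction=attr.na_fraction, ca_fraction=attr.ca_fraction,
        n_upstrokes=attr.n_upstrokes, dominant_frequencies=freqs,
        amplitude_median=amp_med, amplitude_p95=amp_p95,
        min_v_statistics={"min": float(vmin.min()),
                          "median": float(np.median(vmin)),
                          "max": float(vmin.max())},
        ps_counts=ps, ead_present=ead, breaks_occurred=breaks,
        evidence={"t_check": t_check, "t_dev": t_dev, "t_end": t_end,
                  "protocol": protocol, "phase_verdict": phase_verdict,
                  "spectrum_bin_hz": spectrum.bin_width if spectrum else None})


def classify_run(run: RunResult, cfg: AnalysisConfig = AnalysisConfig(),
                 **kw) -> PatternReport:
    return classify_pattern(run.frames, last_stim=run.last_stim_time,
                            protocol=run.config.protocol, cfg=cfg, **kw)


# ---------------------------------------------------------------------------
# phase-wave vs trigger-wave barrier test
# ---------------------------------------------------------------------------

def barrier_verdict(frames: FrameSeries, block: int,
                    cfg: AnalysisConfig = AnalysisConfig(),
                    thickness: int = 1) -> str:
    """Decide phase vs trigger waves from a post-barrier recording.

    Trigger waves (diffusion-mediated) are absorbed by non-conducting
    barriers: activity either dies or stays confined near its source.
    Phase waves are unaffected: the spatial phase profile stays
    continuous across barrier lines.
    """
    nt = frames.times.size
    half = nt // 2
    Vt = frames.V[half:].astype(float)
    amp = Vt.max(axis=0) - Vt.min(axis=0)
    active = amp > cfg.amp_active_min
    if active.mean() < cfg.die_fraction:
        return TRIGGER_WAVES

    dt = frames.frame_interval
    tau = max(1, min(int(round(cfg.tau_ms / dt)), nt - 1))
    ph = phase_map(frames, nt - 1, tau)

    def wrap(d):
        return np.abs((d + np.pi) % (2.0 * np.pi) - np.pi)

    cross, interior = [], []
    for k in range(block, frames.nx, block):
        c = k - 1
        if c + thickness < frames.nx:
            cross.append(wrap(ph[:, c + thickness] - ph[:, c]))
        mid = c - block // 2
        if 0 <= mid < frames.nx - 1:
            interior.append(wrap(ph[:, mid + 1] - ph[:, mid]))
    for k in range(block, frames.ny, block):
        r = k - 1
        if r + thickness < frames.ny:
            cross.append(wrap(ph[r + thickness, :] - ph[r, :]))
        mid = r - block // 2
        if 0 <= mid < frames.ny - 1:
            interior.append(wrap(ph[mid + 1, :] - ph[mid, :]))
    if not cross or not interior:
        raise ValueError("domain too small for the given barrier pitch")
    cross = np.concatenate([c.ravel() for c in cross])
    interior = np.concatenate([c.ravel() for c in interior])
    med_cross = float(np.median(cross))
    med_int = float(np.median(interior))
    continuous = med_cross < max(cfg.phase_ratio_max * med_int,
                                 cfg.phase_jump_max)
    return PHASE_WAVES if continuous else TRIGGER_WAVES


def phase_wave_test(run: RunResult, block: int = 40, *,
                    test_window: float = 2000.0, thickness: int = 1,
                    cfg: AnalysisConfig = AnalysisConfig(),
                    frame_interval: Optional[float] = None) -> str:
    """Continue a developed run with a barrier grid and return the
    verdict (TRIGGER_WAVES or PHASE_WAVES).

    Raises ``ValueError`` when the input pattern is not active at the
    end of the run (nothing to test).
    """
    import dataclasses as _dc

    from .tissue2d import BarrierSpec, run_simulation

    tail = run.frames.V[-1]
    if not (tail > cfg.v_active).any():
        raise ValueError("input run has no sustained activity to test")

    cfg2 = _dc.replace(
        run.config, duration=test_window, protocol="none",
        barrier=BarrierSpec(block=block, thickness=thickness, start_time=0.0),
        frame_interval=(frame_interval if frame_interval is not None
                        else run.config.frame_interval))
    probe = run_simulation(cfg2, initial=run.state.copy())
    return barrier_verdict(probe.frames, block, cfg, thickness)
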