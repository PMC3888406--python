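"""Analysis operators: pseudo-ECG, spectra, attribution, classification."""

import numpy as np
import pytest

from ead2d.pattern_analysis import (AnalysisConfig, ResolutionError,
                                    attribute_waves, barrier_verdict,
                                    classify_pattern,
                                    count_phase_singularities,
                                    interbeat_intervals, line_profile,
                                    mean_power_spectrum, pseudo_ecg,
                                    sustained_activity)
from ead2d.synthetic_fixtures import FixtureSpec, make_movie
from ead2d.tissue2d import FrameSeries


def _movie_from_v(V, dx=0.25, dt_ms=2.0, na=None, ca=None, dtype=np.float32):
    t = np.arange(V.shape[0]) * dt_ms
    return FrameSeries(times=t, V=V.astype(dtype),
                       na=None if na is None else na.astype(dtype),
                       ca=None if ca is None else ca.astype(dtype),
                       dx=dx)


def _ecg_bruteforce(V, dx, electrode):
    """Naive double-loop pseudo-ECG oracle (central differences by hand,
    one-sided at the edges, i.e. np.gradient's convention)."""
    ny, nx = V.shape
    ex, ey, ez = electrode
    total = 0.0
    for yi in range(ny):
        for xi in range(nx):
            if xi == 0:
                gx = (V[yi, 1] - V[yi, 0]) / dx
            elif xi == nx - 1:
                gx = (V[yi, -1] - V[yi, -2]) / dx
            else:
                gx = (V[yi, xi + 1] - V[yi, xi - 1]) / (2 * dx)
            if yi == 0:
                gy = (V[1, xi] - V[0, xi]) / dx
            elif yi == ny - 1:
                gy = (V[-1, xi] - V[-2, xi]) / dx
            else:
                gy = (V[yi + 1, xi] - V[yi - 1, xi]) / (2 * dx)
            x, y = xi * dx, yi * dx
            r = np.sqrt((x - ex) ** 2 + (y - ey) ** 2 + ez ** 2)
            wx = -(x - ex) / r ** 3
            wy = -(y - ey) / r ** 3
            total += (gx * wx + gy * wy) * dx ** 2
    return total


class TestPseudoECG:
    def test_uniform_field_zero(self):
        V = np.full((3, 10, 10), -30.0)
        assert np.all(pseudo_ecg(_movie_from_v(V)).ecg == 0.0)

    def test_symmetric_ramp_cancels(self):
        """Uniform gradient about a centred electrode: the antisymmetric
        weights cancel exactly (the two-opposite-dipoles case)."""
        x = np.arange(11) * 1.0
        V = np.tile(x, (11, 1))[None, :, :]
        e = pseudo_ecg(_movie_from_v(V, dx=1.0))
        assert abs(e.ecg[0]) < 1e-10

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            V = rng.normal(-40.0, 30.0, size=(1, 20, 20))
            fr = _movie_from_v(V, dx=0.3, dtype=np.float64)
            ecg = pseudo_ecg(fr)
            ref = _ecg_bruteforce(V[0], 0.3, ecg.electrode)
            assert ecg.ecg[0] == pytest.approx(ref, rel=1e-12, abs=1e-14)

    def test_plane_wave_biphasic(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", ny=20, nx=20,
                                       duration=400.0))
        ecg = pseudo_ecg(fr)
        assert ecg.ecg.max() > 0 and ecg.ecg.min() < 0

    def test_in_plane_electrode_rejected(self):
        V = np.zeros((1, 8, 8))
        with pytest.raises(ZeroDivisionError):
            pseudo_ecg(_movie_from_v(V, dx=1.0), electrode=(2.0, 3.0, 0.0))


class TestSpectrum:
    def test_pure_tone_single_peak(self):
        t = np.arange(0, 5000.0, 2.0)
        V = np.sin(2 * np.pi * 6.0 * t / 1000.0)[:, None, None] * \
            np.ones((1, 12, 12))
        sp = mean_power_spectrum(_movie_from_v(V))
        assert sp.dominant_frequency == pytest.approx(6.0, abs=sp.bin_width)
        assert len(sp.peaks) == 1

    def test_two_tones_disjoint_halves(self):
        t = np.arange(0, 5000.0, 2.0)
        V = np.zeros((t.size, 12, 12))
        V[:, :, :6] = np.sin(2 * np.pi * 2.0 * t / 1000.0)[:, None, None]
        V[:, :, 6:] = np.sin(2 * np.pi * 3.0 * t / 1000.0)[:, None, None]
        sp = mean_power_spectrum(_movie_from_v(V))
        got = sorted(f for f, _ in sp.peaks[:2])
        assert got[0] == pytest.approx(2.0, abs=sp.bin_width)
        assert got[1] == pytest.approx(3.0, abs=sp.bin_width)

    def test_white_noise_no_peaks(self):
        """Summed periodogram of seeded white noise stays below the 5x
        median peak threshold (Monte-Carlo check over seeds)."""
        for seed in range(5):
            fr, _ = make_movie(FixtureSpec("noise_movie", seed=seed,
                                           ny=16, nx=16, duration=5000.0))
            sp = mean_power_spectrum(fr)
            assert sp.peaks == []

    def test_short_record_resolution_error(self):
        V = np.zeros((100, 8, 8))
        with pytest.raises(ResolutionError, match="Hz"):
            mean_power_spectrum(_movie_from_v(V))

    def test_sublattice_offset_invariance(self):
        fr, _ = make_movie(FixtureSpec("phase_osc_movie", ny=30, nx=30,
                                       duration=5000.0))
        doms = {mean_power_spectrum(fr, n_points=100,
                                    offset=k).dominant_frequency
                for k in (0, 1, 2)}
        assert len(doms) == 1


class TestAttribution:
    def test_na_front_rule(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", na_led=True))
        attr = attribute_waves(fr)
        assert attr.n_upstrokes > 0
        assert attr.na_fraction == 1.0
        assert attr.na_fraction + attr.ca_fraction == pytest.approx(1.0)

    def test_ca_front_rule(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", na_led=False))
        attr = attribute_waves(fr)
        assert attr.n_upstrokes > 0
        assert attr.ca_fraction == 1.0

    def test_empty_attribution_no_upstrokes(self):
        V = np.full((100, 10, 10), -86.0)
        na = np.full_like(V, 0.5)
        attr = attribute_waves(_movie_from_v(V, na=na))
        assert attr.n_upstrokes == 0
        assert attr.na_fraction == 0.0 and attr.ca_fraction == 0.0

    def test_requires_gate_channel(self):
        V = np.full((10, 8, 8), -86.0)
        with pytest.raises(ValueError):
            attribute_waves(_movie_from_v(V))


class TestInterbeat:
    def test_tone_intervals_match_period(self):
        fr, _ = make_movie(FixtureSpec("phase_osc_movie", f_hz=6.0,
                                       ny=10, nx=10, duration=4000.0))
        rep = interbeat_intervals(fr, nodes=[(5, 5)])
        _, ivs, _ = rep.per_node[0]
        assert len(ivs) >= 20
        assert np.allclose(ivs, 1000.0 / 6.0, atol=2.1)

    def test_alternating_amplitudes_two_clusters(self):
        t = np.arange(0.0, 4000.0, 2.0)
        v = np.full_like(t, -80.0)
        for k, on in enumerate(range(100, 3800, 400)):
            amp = 100.0 if k % 2 == 0 else 60.0
            sel = (t >= on) & (t < on + 120)
            v[sel] = -80.0 + amp * np.sin(
                np.pi * (t[sel] - on) / 120.0)
        V = v[:, None, None] * np.ones((1, 4, 4))
        rep = interbeat_intervals(_movie_from_v(V), nodes=[(2, 2)])
        _, ivs, amps = rep.per_node[0]
        # the threshold is crossed at a slightly different phase for the
        # two amplitudes, so intervals alternate around the 400 ms period
        assert np.mean(ivs) == pytest.approx(400.0, abs=5.0)
        assert np.all(np.abs(np.array(ivs) - 400.0) < 50.0)
        lo, hi = min(amps), max(amps)
        assert hi - lo >= 40.0             # two amplitude bands
        assert np.count_nonzero(rep.histogram) == 2

    def test_single_beat_empty(self):
        t = np.arange(0.0, 500.0, 2.0)
        v = np.where((t > 100) & (t < 300), 0.0, -86.0)
        V = v[:, None, None] * np.ones((1, 3, 3))
        rep = interbeat_intervals(_movie_from_v(V), nodes=[(1, 1)])
        assert rep.per_node[0][1] == []


class TestSustainment:
    def test_plane_wave_not_sustained(self):
        fr, _ = make_movie(FixtureSpec("plane_movie"))
        assert not sustained_activity(fr, 3000.0)

    def test_spiral_sustained(self):
        fr, _ = make_movie(FixtureSpec("spiral_movie"))
        assert sustained_activity(fr, 3000.0)

    def test_check_time_beyond_record(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", duration=1000.0))
        with pytest.raises(ValueError):
            sustained_activity(fr, 2000.0)


class TestLineProfile:
    def test_plane_wave_constant_slope_front(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", nx=40, ny=10,
                                       duration=300.0))
        M = line_profile(fr, row=5)
        xs = np.arange(5, 35)
        acts = []
        for x in xs:
            i = np.flatnonzero(M[:, x] > -30.0)
            acts.append(fr.times[i[0]])
        acts = np.array(acts)
        assert np.all(np.diff(acts) >= 0)          # ordered activation
        fit = np.polyfit(xs, acts, 1)
        resid = acts - np.polyval(fit, xs)
        # front line is straight to within one frame interval
        assert np.sqrt(np.mean(resid ** 2)) < fr.frame_interval

    def test_uniform_constant_matrix(self):
        V = np.full((5, 6, 7), -20.0)
        M = line_profile(_movie_from_v(V), col=3)
        assert np.all(M == -20.0)

    def test_index_validation(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", ny=10, nx=10,
                                       duration=100.0))
        with pytest.raises(IndexError):
            line_profile(fr, row=10)
        with pytest.raises(ValueError):
            line_profile(fr)
        with pytest.raises(ValueError):
            line_profile(fr, row=1, col=1)


FIXTURE_MATRIX = [
    (FixtureSpec("plane_movie"), "PLAIN_PROPAGATION"),
    (FixtureSpec("plane_movie", k_eads=1), "NO_SUSTAINED_EAD"),
    (FixtureSpec("spiral_movie"), "SINGLE_SPIRAL"),
    (FixtureSpec("spiral_movie", n_spirals=4, na_led=False, seed=3), "SF_a"),
    (FixtureSpec("spiral_movie", n_spirals=4, na_led=True, seed=4), "SF_b"),
    (FixtureSpec("spiral_movie", n_spirals=2, die_at=2000.0, seed=5),
     "SELF_TERMINATED_SFa"),
    (FixtureSpec("phase_osc_movie"), "OSC"),
]


class TestClassifyPattern:
    @pytest.mark.parametrize("spec,expected",
                             FIXTURE_MATRIX,
                             ids=[e for _, e in FIXTURE_MATRIX])
    def test_fixture_matrix(self, spec, expected):
        fr, truth = make_movie(spec)
        rep = classify_pattern(fr)
        assert truth["label"] == expected
        assert rep.label == expected

    def test_na_fraction_reported_continuously(self):
        fr, _ = make_movie(FixtureSpec("spiral_movie", n_spirals=4,
                                       na_led=True, seed=4))
        rep = classify_pattern(fr)
        assert 0.0 <= rep.na_fraction <= 1.0
        assert rep.na_fraction > 0.2

    def test_report_serializes(self):
        fr, _ = make_movie(FixtureSpec("phase_osc_movie"))
        rep = classify_pattern(fr)
        import json
        back = json.loads(rep.to_json())
        assert back["label"] == "OSC"


class TestPhaseAnalysis:
    def test_single_spiral_one_singularity(self):
        fr, _ = make_movie(FixtureSpec("spiral_movie"))
        tau = int(round(1000.0 / 6.0 / 4 / fr.frame_interval))
        n = count_phase_singularities(fr, fr.times.size - 1, tau)
        assert n == 1

    def test_plane_wave_no_singularity(self):
        fr, _ = make_movie(FixtureSpec("plane_movie", duration=300.0))
        n = count_phase_singularities(fr, fr.times.size - 1, 5)
        assert n == 0


class TestBarrierVerdict:
    @pytest.mark.parametrize("seed", range(5))
    def test_phase_oscillator_vs_target(self, seed):
        osc, _ = make_movie(FixtureSpec("phase_osc_movie", seed=seed,
                                        duration=3000.0))
        assert barrier_verdict(osc, block=10) == "PHASE_WAVES"
        tgt, _ = make_movie(FixtureSpec("target_movie", seed=seed,
                                        barrier_block=10, duration=3000.0))
        assert barrier_verdict(tgt, block=10) == "TRIGGER_WAVES"

    def test_dying_activity_is_trigger(self):
        tgt, _ = make_movie(FixtureSpec("target_movie", die_at=1000.0,
                                        duration=3000.0))
        assert barrier_verdict(tgt, block=10) == "TRIGGER_WAVES"

    def test_phase_test_precondition(self, baseline_params):
        from ead2d.pattern_analysis import phase_wave_test
        from ead2d.tissue2d import TissueConfig, run_simulation
        cfg = TissueConfig(nx=20, ny=20, dx=0.5, duration=10.0,
                           frame_interval=5.0, protocol="none")
        res = run_simulation(cfg)
        with pytest.raises(ValueError, match="sustained"):
            phase_wave_test(res, block=5)
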