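"""2D monodomain solver: Laplacian, boundaries, protocols, barriers."""

import numpy as np
import pytest

from ead2d import _kernels
from ead2d.ionic_model import N_STATE, find_rest_state
from ead2d.tissue2d import (BarrierSpec, CouplingMask, ProtocolError,
                            TissueConfig, TissueState, apply_barrier_grid,
                            laplacian5, run_simulation, step_tissue)


def _ghost_oracle(V, dx):
    """Independent Neumann Laplacian: mirror ghost nodes + plain stencil."""
    P = np.pad(V, 1, mode="edge")
    return (P[:-2, 1:-1] + P[2:, 1:-1] + P[1:-1, :-2] + P[1:-1, 2:]
            - 4.0 * V) / dx ** 2


class TestLaplacian:
    def test_constant_field_zero(self):
        assert np.all(laplacian5(np.full((8, 9), 3.7), 0.5) == 0.0)

    def test_unit_bump_stencil(self):
        V = np.zeros((7, 7))
        V[3, 3] = 1.0
        L = laplacian5(V, 1.0)
        assert L[3, 3] == -4.0
        for y, x in ((2, 3), (4, 3), (3, 2), (3, 4)):
            assert L[y, x] == 1.0
        assert np.count_nonzero(L) == 5

    def test_linear_ramp_zero_under_neumann_oracle(self):
        y, x = np.mgrid[0:10, 0:12]
        V = 2.0 * x + 0.5 * y
        L = laplacian5(V, 0.25)
        oracle = _ghost_oracle(V, 0.25)
        # interior of a linear ramp is exactly harmonic
        assert np.allclose(L[1:-1, 1:-1], 0.0, atol=1e-12)
        assert np.allclose(L, oracle, atol=1e-12)

    def test_random_fields_match_ghost_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            V = rng.normal(size=(20, 20)) * 40.0
            assert np.allclose(laplacian5(V, 0.3), _ghost_oracle(V, 0.3),
                               atol=1e-10)

    def test_masked_edges_zero_flux(self):
        """A fully severed column behaves like two independent Neumann
        domains."""
        rng = np.random.default_rng(1)
        V = rng.normal(size=(10, 14))
        mask = CouplingMask.full(10, 14)
        mask.conn_x[:, 6] = 0    # cut between columns 6 and 7
        L = laplacian5(V, 1.0, mask)
        left = _ghost_oracle(V[:, :7], 1.0)
        right = _ghost_oracle(V[:, 7:], 1.0)
        assert np.allclose(L, np.concatenate([left, right], axis=1),
                           atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            laplacian5(np.zeros((5, 5)), 1.0, CouplingMask.full(6, 5))


class TestConfigValidation:
    def test_stability_bound(self):
        with pytest.raises(ValueError, match="stability"):
            TissueConfig(nx=20, ny=20, dx=0.1, dt=0.05, D=0.00154,
                         duration=1.0)

    def test_grid_minimum(self):
        with pytest.raises(ValueError):
            TissueConfig(nx=5, ny=20)

    def test_frame_interval_multiple_of_dt(self):
        with pytest.raises(ValueError):
            TissueConfig(nx=20, ny=20, frame_interval=0.05, dt=0.02)

    def test_pacing_period_bound(self):
        with pytest.raises(ValueError):
            TissueConfig(nx=20, ny=20, protocol="paced", pacing_period=200.0)

    def test_barrier_spec_validation(self):
        with pytest.raises(ValueError):
            BarrierSpec(block=3)
        with pytest.raises(ValueError):
            BarrierSpec(block=8, thickness=8)


class TestStepTissue:
    def test_uniform_rest_stays_uniform(self, baseline_params):
        cfg = TissueConfig(nx=16, ny=16, dx=0.5, duration=0.0,
                           protocol="none")
        ts = TissueState.at_rest(cfg, baseline_params)
        v0 = ts.V.copy()
        step_tissue(ts, cfg, n_steps=500, params=baseline_params)
        assert np.ptp(ts.V) < 1e-9          # still spatially uniform
        assert np.allclose(ts.V, v0, atol=0.01)

    def test_decoupled_limit_matches_single_cell(self, baseline_params):
        """With D = 0 every node follows the isolated-cell trajectory."""
        cfg = TissueConfig(nx=12, ny=10, dx=0.5, D=0.0, duration=0.0,
                           protocol="none")
        ts = TissueState.at_rest(cfg, baseline_params)
        stim = np.full((10, 12), 20.0)
        step_tissue(ts, cfg, i_stim=stim, n_steps=100, params=baseline_params)
        step_tissue(ts, cfg, n_steps=5000, params=baseline_params)

        S = find_rest_state(baseline_params).to_vector().reshape(1, N_STATE)
        _kernels.advance(S, baseline_params, cfg.dt, 100, np.array([20.0]))
        _kernels.advance(S, baseline_params, cfg.dt, 5000, np.zeros(1))
        assert np.array_equal(ts.S, np.tile(S[0], (120, 1)))

    def test_pure_diffusion_conserves_mean(self):
        """Zero-flux diffusion conserves the spatial mean of V exactly,
        with and without internal barriers."""
        rng = np.random.default_rng(3)
        cfg = TissueConfig(nx=24, ny=20, dx=0.5, duration=0.0,
                           protocol="none", diffusion_only=True)
        ts = TissueState.at_rest(cfg)
        ts.S[:, 0] = rng.normal(-40.0, 30.0, size=480)
        apply_barrier_grid(ts, block=8)
        m0 = ts.V.mean()
        step_tissue(ts, cfg, n_steps=2000)
        assert ts.V.mean() == pytest.approx(m0, abs=1e-10)
        assert np.ptp(ts.V) < np.ptp(ts.S[:, 0].reshape(20, 24)) + 1e-12

    def test_symmetric_stimulus_symmetric_frames(self, baseline_params):
        """A left-right symmetric stimulus on homogeneous tissue keeps the
        frames mirror-symmetric."""
        cfg = TissueConfig(nx=21, ny=14, dx=0.5, duration=0.0,
                           protocol="none")
        ts = TissueState.at_rest(cfg, baseline_params)
        stim = np.zeros((14, 21))
        stim[6:8, 9:12] = 20.0              # centred block
        step_tissue(ts, cfg, i_stim=stim, n_steps=100, params=baseline_params)
        step_tissue(ts, cfg, n_steps=2500, params=baseline_params)
        V = ts.V
        assert np.allclose(V, V[:, ::-1], atol=1e-8)


class TestProtocols:
    def test_p1_plane_wave_crosses_and_returns_to_rest(self, baseline_params):
        cfg = TissueConfig(nx=60, ny=12, dx=0.5, duration=500.0,
                           frame_interval=5.0, protocol="p1",
                           record_gates=False)
        res = run_simulation(cfg)
        V = res.frames.V
        assert V[:, :, -2].max() > 0.0       # wave reached the right edge
        assert V[-1].max() < -75.0           # tissue back at rest
        # activation is ordered left to right
        act = np.array([np.flatnonzero(V[:, 6, x] > -30)[0]
                        for x in (10, 30, 50)])
        assert np.all(np.diff(act) > 0)

    def test_p1_zero_amplitude_no_activation(self):
        cfg = TissueConfig(nx=30, ny=12, dx=0.5, duration=50.0,
                           frame_interval=5.0, protocol="p1",
                           stim_amplitude=0.0, record_gates=False)
        res = run_simulation(cfg)
        assert res.frames.V.max() < -80.0

    def test_p2_s1_failure_raises(self):
        cfg = TissueConfig(nx=30, ny=12, dx=0.5, duration=300.0,
                           protocol="p2", stim_amplitude=0.0,
                           record_gates=False)
        with pytest.raises(ProtocolError):
            run_simulation(cfg)

    def test_p2_fires_s2_after_recovery(self, baseline_params):
        cfg = TissueConfig(nx=50, ny=50, dx=0.5, duration=450.0,
                           frame_interval=5.0, protocol="p2",
                           record_gates=False)
        res = run_simulation(cfg)
        events = {e["event"] for e in res.frames.stim_log}
        assert "front_crossed_mid" in events
        assert "s2_fired" in events
        t_s2 = [e["t"] for e in res.frames.stim_log
                if e["event"] == "s2_fired"][0]
        k = int(np.searchsorted(res.frames.times, t_s2)) - 1
        # the S2 quarter was recovered when S2 fired
        assert res.frames.V[k, :25, :25].max() < -60.0

    def test_stimulus_on_recovered_tissue_plain_wave(self, baseline_params):
        """A premature-style stimulus applied to fully recovered tissue
        just launches an expanding wave, no re-entry."""
        cfg = TissueConfig(nx=40, ny=40, dx=0.5, duration=300.0,
                           frame_interval=5.0, protocol="none",
                           record_gates=False)
        ts = TissueState.at_rest(cfg, baseline_params)
        stim = np.zeros((40, 40))
        stim[:20, :20] = 20.0
        step_tissue(ts, cfg, i_stim=stim, n_steps=100,
                    params=baseline_params)
        step_tissue(ts, cfg, n_steps=14900, params=baseline_params)
        assert ts.V.max() < -75.0            # fully repolarized, no re-entry

    def test_paced_protocol_schedules_multiple_stimuli(self, baseline_params):
        from ead2d.tissue2d import protocol_paced
        cfg = TissueConfig(nx=30, ny=10, dx=0.5, duration=100.0,
                           protocol="paced", pacing_period=400.0,
                           pacing_epoch=1000.0)
        proto = protocol_paced(cfg)
        assert proto.onsets == (0.0, 400.0, 800.0)
        with pytest.raises(ValueError):
            protocol_paced(cfg, period=100.0)


class TestBarriers:
    def test_barrier_confines_activation(self, baseline_params):
        """P1 into a barrier lattice: no wave crosses a barrier line."""
        cfg = TissueConfig(nx=40, ny=40, dx=0.5, duration=150.0,
                           frame_interval=5.0, protocol="p1",
                           barrier=BarrierSpec(block=10), record_gates=False)
        res = run_simulation(cfg)
        # compartments beyond the first column of blocks stay at rest
        assert res.frames.V[:, :, 10:].max() < -80.0
        # the stimulated compartment column did activate
        assert res.frames.V[:, :, :10].max() > -30.0

    def test_empty_barrier_identical_run(self, baseline_params):
        cfg = TissueConfig(nx=24, ny=24, dx=0.5, duration=60.0,
                           frame_interval=5.0, protocol="p1",
                           record_gates=False)
        a = run_simulation(cfg)
        ts = TissueState.at_rest(cfg, baseline_params)
        apply_barrier_grid(ts, block=60)   # pitch beyond the domain: no cuts
        b = run_simulation(cfg, initial=ts)
        assert np.array_equal(a.frames.V, b.frames.V)

    def test_barrier_mask_only_touches_mask(self):
        cfg = TissueConfig(nx=20, ny=20, dx=0.5, duration=0.0)
        ts = TissueState.at_rest(cfg)
        S0 = ts.S.copy()
        apply_barrier_grid(ts, block=5)
        assert np.array_equal(ts.S, S0)
        assert ts.mask.conn_x[:, 4].sum() == 0
        assert ts.mask.conn_y[4, :].sum() == 0


class TestRunSimulation:
    def test_bit_reproducible(self):
        cfg = TissueConfig(nx=20, ny=20, dx=0.5, duration=40.0,
                           frame_interval=5.0, protocol="p1")
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.frames.V, b.frames.V)
        assert np.array_equal(a.frames.na, b.frames.na)

    def test_zero_duration_single_frame(self):
        cfg = TissueConfig(nx=16, ny=16, dx=0.5, duration=0.0)
        res = run_simulation(cfg)
        assert res.frames.V.shape == (1, 16, 16)

    def test_frame_count_and_metadata(self):
        cfg = TissueConfig(nx=16, ny=16, dx=0.5, duration=50.0,
                           frame_interval=10.0, protocol="p1")
        res = run_simulation(cfg)
        assert res.frames.V.shape[0] == 6    # duration/frame_interval + 1
        assert res.frames.meta["config"]["nx"] == 16
        assert np.all(np.isfinite(res.frames.V))

    def test_h5_round_trip(self, tmp_path):
        cfg = TissueConfig(nx=16, ny=16, dx=0.5, duration=20.0,
                           frame_interval=5.0, protocol="p1")
        res = run_simulation(cfg)
        path = tmp_path / "frames.h5"
        res.frames.save_h5(path)
        from ead2d.tissue2d import FrameSeries
        back = FrameSeries.load_h5(path)
        assert np.array_equal(back.V, res.frames.V)
        assert back.dx == res.frames.dx
        assert back.meta["config"]["protocol"] == "p1"
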