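"""Forward-model tests: dark operating point, steady states, integration."""

import numpy as np
import pytest

import photoclamp as pc
from photoclamp.cascade import simulate_current


class TestDarkOperatingPoint:
    def test_dark_cgmp_from_dark_current(self, consensus):
        params, _ = consensus("mouse_cone")
        dark = pc.dark_operating_point(params, 80.0)
        assert dark.G_D == pytest.approx(20.0, rel=1e-12)
        # recording-convention (negative) currents are accepted
        assert pc.dark_operating_point(params, -80.0).G_D == dark.G_D

    def test_current_to_calcium_constant(self, consensus):
        params, _ = consensus("primate_cone")
        dark = pc.dark_operating_point(params.replace(beta=9.0, C_D=1.0), 240.0)
        assert dark.q == pytest.approx(9.0 * 1.0 / 240.0)  # = 0.0375

    def test_max_cyclase_rate(self):
        params = pc.consensus_params("mouse_cone")
        dark = pc.dark_operating_point(params, 80.0)  # G_D = 20
        expected = 20.0 * (761.0 / 9.74) * (1.0 + (1.0 / 0.4) ** 4)
        assert dark.S_max == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.26e4, rel=1e-2)

    def test_dark_pde_activity(self):
        params = pc.consensus_params("primate_rod")
        dark = pc.dark_operating_point(params, 28.0)
        assert dark.P_D == pytest.approx(2.53 / 7.07, rel=1e-12)

    def test_rejects_nonpositive_dark_current(self, consensus):
        params, _ = consensus("mouse_rod")
        with pytest.raises(ValueError):
            pc.dark_operating_point(params, 0.0)


class TestConsensusParams:
    def test_table_values(self):
        assert pc.consensus_params("primate_cone").eta == 2000.0
        assert pc.consensus_params("mouse_rod").sigma == 7.66
        assert pc.consensus_params("primate_cone").beta == 9.0

    @pytest.mark.parametrize("cell_type", pc.CELL_TYPES)
    def test_sigma_phi_tied(self, cell_type):
        p = pc.consensus_params(cell_type)
        assert p.sigma == p.phi

    def test_unknown_type(self):
        with pytest.raises(ValueError, match="unsupported"):
            pc.consensus_params("tiger_cone")


class TestSteadyState:
    def test_zero_background_is_dark_state(self, consensus):
        params, dark = consensus("primate_cone")
        ss = pc.steady_state(params, dark, 0.0)
        assert ss[5] == pytest.approx(dark.I_D, rel=1e-10)
        assert ss[2] == pytest.approx(dark.G_D, rel=1e-10)

    @pytest.mark.parametrize("cell_type", pc.CELL_TYPES)
    def test_current_decreases_with_background(self, cell_type, consensus):
        params, dark = consensus(cell_type)
        scale = 1000.0 if "cone" in cell_type else 1.0
        levels = [0.0, 1 * scale, 5 * scale, 20 * scale]
        currents = [pc.steady_state(params, dark, b)[5] for b in levels]
        assert np.all(np.diff(currents) < 0)

    def test_matches_long_forward_simulation(self, consensus):
        params, dark = consensus("primate_cone")
        ss = pc.steady_state(params, dark, 10000.0)
        dt = 1e-4
        stim = pc.Trace(dt, np.full(int(5.0 / dt), 10000.0), "R*/s")
        dark_state = pc.steady_state(params, dark, 0.0)
        end = pc.simulate(params, dark, stim, initial=dark_state).I.values[-1]
        assert end == pytest.approx(ss[5], rel=1e-3)


class TestSimulate:
    def test_dark_fixed_point_conserved(self, consensus):
        params, dark = consensus("mouse_rod")
        dt = 1e-3
        stim = pc.Trace(dt, np.zeros(int(10.0 / dt)), "R*/s")
        st = pc.simulate(params, dark, stim)
        drift = np.max(np.abs(st.I.values - dark.I_D)) / dark.I_D
        assert drift < 1e-3

    def test_channel_current_relation_pointwise(self, consensus):
        params, dark = consensus("primate_cone")
        stim = pc.sinusoid_stimulus(5000.0, 0.8, 2.0, 1.0, 1e-4)
        st = pc.simulate(params, dark, stim)
        assert np.allclose(st.I.values, params.k * st.G.values ** params.n)
        for tr in (st.R, st.P, st.G, st.S, st.C, st.I):
            assert np.all(tr.values >= 0)

    def test_saturating_step_closes_channels(self, consensus):
        params, dark = consensus("primate_rod")
        dt = 1e-3
        stim = pc.Trace(dt, np.full(int(5.0 / dt), 5000.0), "R*/s")
        st = pc.simulate(params, dark, stim,
                         initial=pc.steady_state(params, dark, 0.0))
        assert st.I.values[-1] < 0.01 * dark.I_D

    def test_small_signal_linearity(self, consensus):
        params, dark = consensus("primate_cone")
        eps = 2.0  # R* per flash, deep in the linear range at this mean
        r1, _ = pc.flash_response(params, dark, 5000.0, eps)
        r2, _ = pc.flash_response(params, dark, 5000.0, 2 * eps)
        peak1 = np.max(np.abs(r1.values))
        peak2 = np.max(np.abs(r2.values))
        assert peak2 / peak1 == pytest.approx(2.0, rel=0.01)
        assert peak1 < 0.05 * dark.I_D

    def test_euler_converges_on_halved_step(self, consensus):
        params, dark = consensus("primate_cone")
        dt = 1e-4
        stim = pc.make_variable_mean_noise([2000.0, 20000.0], 0.5, 0.5, dt, seed=7)
        i_ref = simulate_current(params, dark, stim)
        stim_half = pc.Trace(dt / 2, np.repeat(stim.values, 2), "R*/s")
        i_half = simulate_current(params, dark, stim_half)[::2]
        rel_rms = np.sqrt(np.mean((i_ref - i_half) ** 2)) / np.std(i_ref)
        assert rel_rms < 0.005

    def test_rk4_agrees_with_euler(self, consensus):
        params, dark = consensus("mouse_cone")
        stim = pc.sinusoid_stimulus(5000.0, 0.5, 2.0, 0.5, 1e-4)
        e = pc.simulate(params, dark, stim, method="euler").I.values
        r = pc.simulate(params, dark, stim, method="rk4").I.values
        assert np.sqrt(np.mean((e - r) ** 2)) / np.std(e) < 0.005

    def test_rejects_negative_stimulus(self, consensus):
        params, dark = consensus("mouse_cone")
        with pytest.raises(ValueError):
            pc.Trace(1e-4, np.array([-1.0, 0.0]), "R*/s")

    def test_sigma_phi_fitting_degeneracy(self):
        """The opsin and PDE decay rates are interchangeable in fitting:
        starting a fit from the swapped assignment reaches the same fit
        quality (within 1%) as the generating parameters."""
        truth = pc.consensus_params("mouse_rod").replace(sigma=6.0, phi=10.0)
        dark = pc.dark_operating_point(truth, 20.0)
        proto = pc.ProtocolSpec(
            "variable_mean_noise",
            {"mean_levels": [5.0, 25.0, 75.0], "segment_dur": 2.0,
             "contrast": 0.5}, seed=6, dt=1e-3)
        _, clean = pc.make_synthetic_recording(proto, truth, dark, 0.0)
        sd = 0.01 * float(np.std(clean.values))
        stim, resp = pc.make_synthetic_recording(proto, truth, dark, sd)
        cell = pc.CellData([stim], [resp], 20.0)
        spec = pc.FitSpec(shared_params=("sigma", "phi"), tie_sigma_phi=False)
        model = pc.PhototransductionModel([cell], truth, spec)
        mse_truth = model.mse(model._pack(truth, [truth.gamma]))
        swapped = truth.replace(sigma=10.0, phi=6.0)
        res = model.fit(start_params=swapped, restarts=2)
        assert res.mse_value <= 1.01 * mse_truth


class TestFlashResponse:
    def test_cone_kinetics_ratio(self, consensus):
        """Dark-adapted mouse cone flash responses peak ~twofold later than
        primate cone responses."""
        pp, dp = consensus("primate_cone")
        pm, dm = consensus("mouse_cone")
        _, ttp_p = pc.flash_response(pp, dp, 0.0, 20.0)
        _, ttp_m = pc.flash_response(pm, dm, 0.0, 20.0)
        assert ttp_m / ttp_p == pytest.approx(2.0, rel=0.25)

    def test_zero_flash_signals(self, consensus):
        params, dark = consensus("primate_cone")
        with pytest.raises(ValueError, match="undefined"):
            pc.flash_response(params, dark, 1000.0, 0.0)

    def test_dim_flash_time_to_peak_strength_invariant(self, consensus):
        """Time-to-peak is nearly strength-independent for dim flashes (the
        broad rod peak shifts by a few % per doubling, shrinking as the
        flash weakens)."""
        params, dark = consensus("mouse_rod")
        _, t1 = pc.flash_response(params, dark, 10.0, 0.25)
        _, t2 = pc.flash_response(params, dark, 10.0, 0.5)
        assert abs(t1 - t2) / t1 < 0.03
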