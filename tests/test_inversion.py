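"""Inversion tests: each step's algebra, the exact round trip, and the
regularization of noisy estimates."""

import numpy as np
import pytest

import photoclamp as pc
from photoclamp.inversion import (
    InversionSettings,
    current_to_calcium,
    current_to_cgmp,
    invert_current,
    pde_from_cgmp,
    stimulus_from_pde,
)


@pytest.fixture(params=pc.CELL_TYPES)
def cell(request, consensus):
    params, dark = consensus(request.param)
    return params, dark


def _variable_mean_fixture(cell_type, seed=3):
    dt = pc.default_dt(cell_type)
    levels = pc.default_mean_levels(cell_type)
    return pc.make_variable_mean_noise(levels, 1.0, 0.5, dt, seed=seed)


class TestCurrentToCgmp:
    def test_dark_values(self, consensus):
        params, _ = consensus("mouse_cone")
        I = pc.Trace(1e-4, np.full(100, 80.0), "pA")
        G = current_to_cgmp(I, params)
        assert np.allclose(G.values, 20.0)

    def test_round_trip_machine_precision(self, consensus):
        params, _ = consensus("primate_rod")
        rng = np.random.default_rng(1)
        I = pc.Trace(1e-3, rng.uniform(5, 30, 1000), "pA")
        G = current_to_cgmp(I, params)
        back = params.k * G.values ** params.n
        assert np.allclose(back, I.values, rtol=1e-14)

    def test_power_law_scaling(self, consensus):
        params, _ = consensus("primate_cone")  # n = 3
        I = pc.Trace(1e-4, np.full(10, 100.0), "pA")
        g1 = current_to_cgmp(I, params).values[0]
        g2 = current_to_cgmp(pc.Trace(1e-4, I.values / 2, "pA"), params).values[0]
        assert g2 / g1 == pytest.approx(2 ** (-1 / 3))

    def test_rejects_saturated_current(self, consensus):
        params, _ = consensus("mouse_rod")
        with pytest.raises(ValueError, match="saturated"):
            current_to_cgmp(pc.Trace(1e-3, np.array([5.0, 0.0, 5.0]), "pA"), params)


class TestCurrentToCalcium:
    def test_dark_current_gives_dark_calcium(self, consensus):
        params, dark = consensus("primate_cone")
        I = pc.Trace(1e-4, np.full(1000, dark.I_D), "pA")
        C = current_to_calcium(I, dark, params)
        assert np.allclose(C.values, params.C_D, rtol=1e-10)

    def test_constant_current_steady_state(self, consensus):
        params, dark = consensus("mouse_cone")
        I = pc.Trace(1e-4, np.full(2000, 30.0), "pA")
        C = current_to_calcium(I, dark, params)
        assert np.allclose(C.values, dark.q * 30.0 / params.beta, rtol=1e-10)

    def test_time_and_frequency_domains_agree(self, consensus):
        params, dark = consensus("primate_cone")
        rng = np.random.default_rng(5)
        # zero-mean fluctuation around the dark current, periodic enough for
        # the circular frequency-domain solution to match
        n = 2 ** 14
        noise = rng.normal(0, 5.0, n)
        from scipy.ndimage import gaussian_filter1d
        noise = gaussian_filter1d(noise, 20, mode="wrap")
        I = pc.Trace(1e-4, dark.I_D + noise, "pA")
        ct = current_to_calcium(I, dark, params, domain="time").values
        cf = current_to_calcium(I, dark, params, domain="frequency").values
        # discard the extrusion transient of the time-domain solution; the
        # remaining mismatch is the first-order discretization error of the
        # Euler recursion (which mirrors the simulator) vs the exact
        # continuous transfer function
        n0 = n // 2
        rel = np.sqrt(np.mean((ct[n0:] - cf[n0:]) ** 2)) / np.std(ct[n0:])
        assert rel < 5e-3


class TestPdeAndStimulusSteps:
    def test_dark_pde_recovered(self, consensus):
        params, dark = consensus("primate_rod")
        n = 500
        G = pc.Trace(1e-3, np.full(n, dark.G_D), "uM")
        C = pc.Trace(1e-3, np.full(n, params.C_D), "uM")
        P = pde_from_cgmp(G, C, params, dark)
        assert np.allclose(P.values, params.eta / params.phi, rtol=1e-10)

    def test_dark_pde_gives_zero_stimulus(self, consensus):
        params, dark = consensus("primate_rod")
        P = pc.Trace(1e-3, np.full(500, params.eta / params.phi), "s^-1")
        stim = stimulus_from_pde(P, params)
        assert np.allclose(stim.values, 0.0, atol=1e-10)

    def test_pde_offset_maps_to_stimulus_offset(self, consensus):
        """A constant PDE increment c produces a steady stimulus increment
        of phi*sigma*c/gamma."""
        params, dark = consensus("mouse_rod")
        c = 0.5
        P = pc.Trace(1e-3, np.full(500, params.eta / params.phi + c), "s^-1")
        stim = stimulus_from_pde(P, params)
        expected = params.phi * params.sigma * c / params.gamma
        assert np.allclose(stim.values, expected, rtol=1e-10)

    def test_recovered_pde_matches_simulation(self, consensus):
        params, dark = consensus("mouse_cone")
        stim = _variable_mean_fixture("mouse_cone")
        st = pc.simulate(params, dark, stim)
        P = pde_from_cgmp(st.G, st.C, params, dark)
        err = P.values[:-1] - st.P.values[:-1]
        assert np.sqrt(np.mean(err ** 2)) / np.std(st.P.values) < 1e-3


class TestFullInversion:
    def test_round_trip_on_variable_mean_fixture(self, cell):
        """invert(simulate(stim)) recovers the stimulus: the inversion is
        exact up to the extrapolated final samples."""
        params, dark = cell
        stim = _variable_mean_fixture(params.cell_type)
        current = pc.simulate(params, dark, stim).I
        est = invert_current(current, params, dark)
        fv = pc.fraction_variance(stim.values, est.values)
        assert fv > 0.999
        interior = slice(0, -3)
        err = est.values[interior] - stim.values[interior]
        assert np.sqrt(np.mean(err ** 2)) / np.std(stim.values) < 1e-6

    def test_dark_current_gives_zero_stimulus(self, consensus):
        params, dark = consensus("primate_cone")
        I = pc.Trace(1e-4, np.full(1000, dark.I_D), "pA")
        est = invert_current(I, params, dark)
        assert np.allclose(est.values, 0.0, atol=1e-8)

    def test_central_scheme_accurate_on_smooth_stimuli(self, consensus):
        """Central differences recover band-limited stimuli accurately (on
        broadband stimuli only the Euler-mirror scheme is exact, since
        central differences mis-estimate derivatives near Nyquist)."""
        params, dark = consensus("primate_cone")
        stim = pc.sinusoid_stimulus(10000.0, 0.8, 5.0, 2.0, 1e-4)
        current = pc.simulate(params, dark, stim).I
        est = invert_current(current, params, dark,
                             InversionSettings(derivative_scheme="central"))
        err = est.values[5:-5] - stim.values[5:-5]
        # residual is the first-order discretization mismatch between the
        # central stencil and the simulator's forward-Euler steps
        assert np.sqrt(np.mean(err ** 2)) / np.std(stim.values) < 5e-3

    def test_noise_degrades_band_limited_estimate(self, consensus):
        params, dark = consensus("primate_cone")
        stim = _variable_mean_fixture("primate_cone")
        current = pc.simulate(params, dark, stim).I
        rng = np.random.default_rng(12)
        settings = InversionSettings(apply_band_limit=True)
        fvs = []
        for sd in (0.0, 0.5, 2.0):
            noisy = pc.Trace(current.dt,
                             current.values + rng.normal(0, sd, len(current)),
                             "pA")
            est = invert_current(noisy, params, dark, settings)
            fvs.append(pc.fraction_variance(stim.values, est.values))
        assert fvs[0] > fvs[1] > fvs[2]

    def test_spectrum_matching_postcondition(self, consensus):
        params, dark = consensus("primate_cone")
        stim = _variable_mean_fixture("primate_cone")
        current = pc.simulate(params, dark, stim).I
        rng = np.random.default_rng(7)
        noisy = pc.Trace(current.dt,
                         current.values + rng.normal(0, 1.0, len(current)), "pA")
        ref = np.abs(np.fft.rfft(stim.values))
        est = invert_current(noisy, params, dark,
                             InversionSettings(match_power_spectrum=True,
                                               reference_spectrum=ref))
        got = np.abs(np.fft.rfft(est.values))
        nz = ref > 1e-9 * ref.max()
        assert np.allclose(got[nz], ref[nz], rtol=1e-8)

    def test_residual_spectrum_behavior(self, consensus):
        """Stimulus and residual spectra diverge at low frequency and the
        convergence frequency grows with response SNR."""
        params, dark = consensus("primate_cone")
        stim = _variable_mean_fixture("primate_cone")
        current = pc.simulate(params, dark, stim).I
        rng = np.random.default_rng(21)
        settings = InversionSettings(apply_band_limit=True)
        convs = []
        for sd in (0.5, 0.05):
            noisy = pc.Trace(current.dt,
                             current.values + rng.normal(0, sd, len(current)),
                             "pA")
            est = invert_current(noisy, params, dark, settings)
            _, p_stim, p_resid, conv = pc.residual_spectra(stim, est)
            assert conv is not None
            convs.append(conv)
        # the cleaner recording recovers a wider band, and its estimate is
        # accurate at the lowest analyzed frequencies
        assert convs[1] > convs[0]
        assert p_resid[1] < 0.5 * p_stim[1]
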