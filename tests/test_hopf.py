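import dataclasses

import numpy as np
import pytest

from fpsubnet import hopf


def _uncoupled(n=1, a=0.09, f=0.05, xi=0.0, duration=140.0, discard=40.0, seed=1):
    return hopf.HopfConfig(
        n_o=n,
        a=a,
        omega=2 * np.pi * np.full(n, f),
        d=np.zeros((n, n)),
        coupling=0.0,
        xi=xi,
        dt=0.01,
        duration=duration,
        transient_discard=discard,
        seed=seed,
    )


class TestConfigValidation:
    def test_asymmetric_coupling_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hopf.HopfConfig(2, 0.1, 2 * np.pi * np.ones(2), d)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            hopf.HopfConfig(2, 0.1, np.ones(2), np.eye(2))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            hopf.HopfConfig(1, 0.1, np.zeros(1), np.zeros((1, 1)))


class TestFrequencies:
    def test_zero_sd_degenerate(self):
        omega = hopf.sample_frequencies(0.04, 0.0, 5, seed=0)
        assert np.allclose(omega, 2 * np.pi * 0.04)

    def test_moments(self):
        omega = hopf.sample_frequencies(0.04, 0.01, 10000, seed=1)
        f = omega / (2 * np.pi)
        assert abs(f.mean() - 0.04) < 3 * 0.01 / np.sqrt(10000)
        assert abs(f.std() - 0.01) < 0.001

    def test_truncated_positive(self):
        omega = hopf.sample_frequencies(0.005, 0.02, 2000, seed=2)
        assert (omega > 0).all()


class TestSimulate:
    def test_limit_cycle_radius(self):
        traj = hopf.simulate_hopf(_uncoupled(n=2, a=0.09))
        radius = np.sqrt(traj.x_post**2 + traj.y_post**2).mean(axis=1)
        assert np.allclose(radius, 0.3, rtol=0.01)

    def test_subcritical_decay(self):
        traj = hopf.simulate_hopf(_uncoupled(a=-0.075))
        final = np.abs(traj.x[:, -1] + 1j * traj.y[:, -1])
        assert (final < 1e-3).all()

    def test_rms_closed_form(self):
        traj = hopf.simulate_hopf(_uncoupled(a=0.09))
        assert traj.rms()[0] == pytest.approx(np.sqrt(0.09 / 2), rel=0.01)

    def test_deterministic_under_seed(self):
        cfg = _uncoupled(n=3, xi=0.02, duration=30.0, discard=5.0, seed=7)
        t1 = hopf.simulate_hopf(cfg)
        t2 = hopf.simulate_hopf(cfg)
        assert np.array_equal(t1.x, t2.x)
        assert np.array_equal(t1.y, t2.y)

    def test_dt_halving_guard(self):
        # integration accuracy: halving dt changes summaries < 2%
        base = hopf.preset_config("4", duration=100.0, transient_discard=20.0, seed=3)
        fine = dataclasses.replace(base, dt=0.005, xi=0.0)
        coarse = dataclasses.replace(base, dt=0.01, xi=0.0)
        rc = hopf.kuramoto_order(hopf.simulate_hopf(coarse))[1]
        rf = hopf.kuramoto_order(hopf.simulate_hopf(fine))[1]
        assert abs(rc - rf) / rf < 0.02
        rmsc = hopf.simulate_hopf(dataclasses.replace(coarse, a=np.full(4, 0.05))).rms().mean()
        rmsf = hopf.simulate_hopf(dataclasses.replace(fine, a=np.full(4, 0.05))).rms().mean()
        assert abs(rmsc - rmsf) / rmsf < 0.02

    def test_blowup_detected(self):
        cfg = hopf.HopfConfig(
            1, 5.0, np.array([0.25]), np.zeros((1, 1)), dt=3.0, duration=3000.0,
            transient_discard=0.0, xi=0.0,
        )
        with np.errstate(all="ignore"), pytest.raises(RuntimeError, match="blow-up"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hopf.simulate_hopf(cfg)


class TestKuramoto:
    def test_identical_signals(self):
        t = np.arange(0, 50, 0.01)
        sig = np.sin(2 * np.pi * 0.05 * t)
        r_t, r = hopf.kuramoto_order(np.vstack([sig, sig, sig]))
        assert r == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(r_t, 1.0, atol=1e-9)

    def test_four_equally_spaced_phases(self):
        t = np.arange(0, 100, 0.01)
        sigs = [np.sin(2 * np.pi * 0.05 * t + k * np.pi / 2) for k in range(4)]
        _, r = hopf.kuramoto_order(np.vstack(sigs))
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_detuned_pair_two_over_pi(self):
        cfg = hopf.HopfConfig(
            n_o=2, a=0.09, omega=2 * np.pi * np.array([0.05, 0.03]),
            d=np.zeros((2, 2)), coupling=0.0, xi=0.0, dt=0.01,
            duration=270.0, transient_discard=20.0, seed=1,
        )
        _, r = hopf.kuramoto_order(hopf.simulate_hopf(cfg))
        assert r == pytest.approx(2 / np.pi, abs=0.02)

    def test_r_bounded(self, rng):
        x = rng.standard_normal((5, 2000))
        r_t, r = hopf.kuramoto_order(x)
        assert (r_t >= 0).all() and (r_t <= 1 + 1e-12).all()

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hopf.kuramoto_order(np.vstack([np.ones(100), np.arange(100.0)]))


class TestSweep:
    def test_r_nondecreasing_in_coupling(self):
        base = hopf.preset_config("4", duration=100.0, seed=0)
        res = hopf.parameter_sweep(
            np.array([-0.075]), np.array([0.0, 0.1, 0.5, 2.0]), base, reps=3, seed=1
        )
        r = res["mean_r"].ravel()
        from scipy import stats as sps

        rho, p = sps.spearmanr(np.arange(len(r)), r)
        assert rho > 0

    def test_working_point_intermediate(self):
        base = hopf.preset_config("4", duration=100.0, seed=0)
        res = hopf.parameter_sweep(
            np.array([-0.075]), np.array([0.0, 0.1, 2.0]), base, reps=3, seed=1
        )
        assert res["working_point_intermediate"]

    def test_supercritical_rms_above_noise(self):
        base = hopf.preset_config("4", duration=100.0, seed=0)
        res = hopf.parameter_sweep(
            np.array([0.09]), np.array([0.0]), base, reps=2, seed=2
        )
        assert res["mean_rms"][0, 0] == pytest.approx(np.sqrt(0.09 / 2), rel=0.15)
        assert res["mean_rms"][0, 0] > 3 * base.xi

    def test_rms_monotone_in_bifurcation_parameter(self):
        base = hopf.preset_config("4", duration=100.0, seed=0)
        res = hopf.parameter_sweep(
            np.array([-0.05, 0.0, 0.05, 0.1]), np.array([0.0]), base, reps=2, seed=3
        )
        rms = res["mean_rms"].ravel()
        assert (np.diff(rms) > 0).all()

    def test_empty_grid_rejected(self):
        base = hopf.preset_config("4", duration=30.0, seed=0)
        with pytest.raises(ValueError):
            hopf.parameter_sweep(np.array([]), np.array([0.1]), base)


class TestGroupedConfig:
    def test_singleton_reduction(self):
        d4 = hopf.default_group_coupling()
        cfg = hopf.build_grouped_config(
            {"SN-A": 1, "SN-B": 1, "DM": 1, "DA": 1}, d4, seed=5
        )
        assert np.allclose(cfg.d, d4)

    def test_192_preset(self):
        cfg = hopf.preset_config("192", seed=0)
        assert cfg.n_o == 192
        assert len(cfg.groups["SN-A"]) == 30
        assert len(cfg.groups["SN-B"]) == 31
        assert len(cfg.groups["DM"]) == 79
        assert len(cfg.groups["DA"]) == 52

    def test_400_preset_background(self):
        cfg = hopf.preset_config("400", seed=0)
        assert cfg.n_o == 400
        assert len(cfg.groups["other"]) == 208

    def test_total_intergroup_coupling_preserved(self):
        d4 = hopf.default_group_coupling()
        c4 = hopf.build_grouped_config({"SN-A": 1, "SN-B": 1, "DM": 1, "DA": 1}, d4, seed=0)
        c192 = hopf.preset_config("192", seed=0)
        assert c192.d.sum() == pytest.approx(c4.d.sum())

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            hopf.build_grouped_config({"SN-A": 1, "SN-B": 1}, np.zeros((3, 3)))


class TestAblation:
    def test_zeroes_coupling_only(self):
        cfg = hopf.preset_config("4", seed=0)
        ab = hopf.ablate_coupling(cfg)
        assert not ab.d.any()
        assert np.array_equal(ab.a, cfg.a)
        assert np.array_equal(ab.omega, cfg.omega)
        assert ab.xi == cfg.xi

    def test_idempotent(self):
        cfg = hopf.preset_config("4", seed=0)
        ab1 = hopf.ablate_coupling(cfg)
        ab2 = hopf.ablate_coupling(ab1)
        assert np.array_equal(ab1.d, ab2.d)


class TestExperiments:
    def test_amplitude_experiment_table_shape(self):
        cfg = hopf.preset_config("4", duration=60.0, seed=0)
        res = hopf.amplitude_experiment(
            cfg, "SN-A", np.linspace(-0.06, 0.06, 5), reps=2, seed=1
        )
        assert len(res["table"]) == 10
        assert {"a_target", "rms_target", "fc_fp_dm_corrected"} <= set(res["table"].columns)

    def test_rms_increases_with_target_a(self):
        cfg = hopf.preset_config("4", duration=120.0, seed=0)
        res = hopf.amplitude_experiment(
            cfg, "SN-A", np.linspace(-0.07, 0.08, 8), reps=3, seed=2
        )
        tab = res["table"].groupby("a_target")["rms_target"].mean()
        assert tab.iloc[-1] > tab.iloc[0]

    def test_unknown_group_rejected(self):
        cfg = hopf.preset_config("4", duration=30.0, seed=0)
        with pytest.raises(ValueError, match="group"):
            hopf.amplitude_experiment(cfg, "SN-C", reps=1, seed=0)

    def test_census_unbiased_when_uncoupled(self):
        cfg = hopf.ablate_coupling(hopf.preset_config("4", duration=120.0, seed=0))
        res = hopf.anticorrelation_census(cfg, n_runs=80, seed=3)
        # independence -> symmetric sign: count within 3 binomial SE of half
        assert abs(res["count"] - 40) < 3 * np.sqrt(80 * 0.25) + 1

    def test_census_single_run(self):
        cfg = hopf.preset_config("4", duration=40.0, seed=0)
        res = hopf.anticorrelation_census(cfg, n_runs=1, seed=4)
        assert res["count"] in (0, 1)
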