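"""Simulator: rate laws, exact stochastic paths, camera emission, cohorts."""

import math

import numpy as np
import pytest
from scipy.linalg import null_space

from fretfold.simulate import (
    ConstantLaw,
    HillLaw,
    KineticScheme,
    Photophysics,
    StateModel,
    StatePath,
    emit_intensities,
    evaluate_rate_law,
    generate_cohort,
    generate_isotherm,
    simulate_path,
    stationary_distribution,
)
from fretfold.traces import compute_fret


class TestRateLaws:
    def test_hill_half_saturation(self):
        law = HillLaw(k_max=1.22, K_D=310.0, n=3.1)
        assert evaluate_rate_law(law, 310.0) == pytest.approx(0.61, abs=1e-12)

    def test_constant_ignores_concentration(self):
        law = ConstantLaw(0.18)
        for c in (0.0, 75.0, 1e6):
            assert evaluate_rate_law(law, c) == 0.18

    def test_hill_matches_log_space_evaluation(self):
        # independent evaluation of the same law through logarithms
        law = HillLaw(k_max=1.22, K_D=310.0, n=3.1)
        c = 75.0
        log_r = law.n * (math.log(c) - math.log(law.K_D))
        expected = law.k_max / (1.0 + math.exp(-log_r))
        assert evaluate_rate_law(law, c) == pytest.approx(expected, abs=1e-12)

    def test_hill_limits(self):
        law = HillLaw(k_max=2.0, K_D=100.0, n=2.0, basal=0.01)
        assert evaluate_rate_law(law, 0.0) == 0.01
        assert evaluate_rate_law(law, 1e9) == pytest.approx(2.01, rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rate_law(ConstantLaw(1.0), -1.0)


class TestSimulatePath:
    def test_single_state_spans_duration(self):
        scheme = KineticScheme(("U",), np.zeros((1, 1)))
        path = simulate_path(scheme, 12.5, seed=0)
        assert path.segments == [("U", 0.0, 12.5)]

    def test_symmetric_two_state_occupancy(self):
        scheme = KineticScheme(("A", "B"), np.array([[0, 0.5], [0.5, 0]]))
        path = simulate_path(scheme, 2e4, seed=1)
        occ = path.occupancy()
        assert occ["A"] == pytest.approx(0.5, abs=0.03)

    def test_three_state_occupancy_matches_nullspace_oracle(self):
        # six rates in the spirit of the three-state aptamer scheme
        rates = np.array([
            [0.0, 0.50, 0.023],
            [0.35, 0.0, 0.014],
            [0.0025, 0.036, 0.0],
        ])
        scheme = KineticScheme(("U", "F_LF", "F_LB"), rates)
        q = rates.copy()
        np.fill_diagonal(q, -q.sum(axis=1))
        ns = null_space(q.T)[:, 0]
        pi_oracle = ns / ns.sum()

        path = simulate_path(scheme, 1.2e5, seed=7)
        occ = path.occupancy()
        for i, lbl in enumerate(scheme.states):
            assert occ[lbl] == pytest.approx(pi_oracle[i], abs=0.01)

    def test_dwell_means_match_exit_rates(self):
        k12, k21 = 0.8, 0.3
        scheme = KineticScheme(("A", "B"), np.array([[0, k12], [k21, 0]]))
        path = simulate_path(scheme, 5e4, seed=3)
        for lbl, k in (("A", k12), ("B", k21)):
            dw = [t1 - t0 for s, t0, t1 in path.segments[1:-1] if s == lbl]
            se = (1 / k) / math.sqrt(len(dw))
            assert np.mean(dw) == pytest.approx(1 / k, abs=3 * se)

    def test_absorbing_state_yields_single_dwell(self):
        scheme = KineticScheme(("A", "B"), np.array([[0, 2.0], [0.0, 0]]))
        path = simulate_path(scheme, 50.0, seed=4, initial_state="A")
        assert path.segments[-1][0] == "B"
        assert path.segments[-1][2] == 50.0

    def test_stationary_distribution_helper(self):
        q = np.array([[-1.0, 1.0], [0.25, -0.25]])
        pi = stationary_distribution(q)
        assert pi @ q == pytest.approx(np.zeros(2), abs=1e-12)
        assert pi.sum() == pytest.approx(1.0)


class TestEmission:
    def test_noiseless_no_leakage_splits_total(self, noiseless_photophysics):
        sm = StateModel(("A", "B"), (0.5, 0.9), (0.05, 0.05))
        path = StatePath([("A", 0.0, 1.0)])
        ph = Photophysics(total_intensity=1000.0, noise_sd=0.0,
                          leakage_fraction=0.0, bleach_lifetime=None)
        tr = emit_intensities(path, sm, 0.05, ph, seed=0)
        assert np.allclose(tr.donor, 500.0)
        assert np.allclose(tr.acceptor, 500.0)

    def test_leakage_only_channel_photon_fraction_zero(self):
        # raw-photon-fraction mode: a dark-acceptor state shows pure leakage
        sm = StateModel(("dark", "bright"), (0.0, 0.9), (0.01, 0.01))
        path = StatePath([("dark", 0.0, 1.0)])
        ph = Photophysics(total_intensity=1000.0, noise_sd=0.0,
                          leakage_fraction=0.12, bleach_lifetime=None,
                          means_are_apparent=False)
        tr = emit_intensities(path, sm, 0.05, ph, seed=0)
        assert np.allclose(tr.acceptor, 0.12 * tr.donor)

    def test_round_trip_recovers_apparent_state_means(self, three_state_model):
        path = StatePath([("U", 0.0, 1.0), ("F_LF", 1.0, 2.0),
                          ("F_LB", 2.0, 3.0)])
        ph = Photophysics(noise_sd=0.0, leakage_fraction=0.12,
                          bleach_lifetime=None)
        tr = emit_intensities(path, three_state_model, 0.05, ph, seed=0)
        ft = compute_fret(tr, alpha=ph.alpha, detect_bleaching=False)
        expected = np.repeat(three_state_model.fret_means, 20)
        assert np.max(np.abs(ft.e_app - expected)) < 1e-9

    def test_transition_frame_is_time_weighted(self, noiseless_photophysics):
        sm = StateModel(("A", "B"), (0.2, 0.8), (0.05, 0.05))
        # switch at 0.025 s: frame 0 spends half its time in each state
        path = StatePath([("A", 0.0, 0.025), ("B", 0.025, 0.05)])
        ph = Photophysics(noise_sd=0.0, leakage_fraction=0.0,
                          bleach_lifetime=None)
        tr = emit_intensities(path, sm, 0.05, ph, seed=0)
        e = tr.acceptor[0] / (tr.donor[0] + tr.acceptor[0])
        assert e == pytest.approx(0.5, abs=1e-12)

    def test_bleach_truncates_signal(self, two_state_model):
        path = StatePath([("U", 0.0, 100.0)])
        ph = Photophysics(noise_sd=0.0, bleach_lifetime=5.0)
        tr = emit_intensities(path, two_state_model, 0.05, ph, seed=11)
        assert tr.bleach_frame is not None
        assert np.all(tr.donor[tr.bleach_frame:] == 0.0)
        assert np.all(tr.acceptor[tr.bleach_frame:] == 0.0)

    def test_invalid_frame_dt_rejected(self, two_state_model):
        path = StatePath([("U", 0.0, 1.0)])
        with pytest.raises(ValueError):
            emit_intensities(path, two_state_model, 0.0)


class TestCohort:
    def test_seed_determinism(self, two_state_scheme, two_state_model):
        kw = dict(n_molecules=3, frame_dt=0.05, duration=5.0, seed=42)
        t1, m1 = generate_cohort(two_state_scheme, two_state_model, **kw)
        t2, m2 = generate_cohort(two_state_scheme, two_state_model, **kw)
        assert m1 == m2
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.donor, b.donor)
            np.testing.assert_array_equal(a.acceptor, b.acceptor)

    def test_cohort_size_and_manifest(self, two_state_scheme, two_state_model):
        trs, manifest = generate_cohort(two_state_scheme, two_state_model,
                                        25, 0.05, 2.0, seed=0)
        assert len(trs) == 25
        assert manifest["n_molecules"] == 25
        assert manifest["condition"]["lysine_uM"] == 300.0

    def test_first_frame_states_follow_stationary_distribution(self):
        # 70/30 folded/unfolded equilibrium, as at 10 mM Mg2+
        k_unfold = 0.3
        k_fold = k_unfold * 0.7 / 0.3
        sm = StateModel(("U", "F_LF"), (0.32, 0.60), (0.05, 0.05))
        scheme = KineticScheme(("U", "F_LF"),
                               np.array([[0, k_fold], [k_unfold, 0]]))
        trs, _ = generate_cohort(scheme, sm, 1500, 0.05, 1.0,
                                 Photophysics(noise_sd=0.0,
                                              bleach_lifetime=None), seed=5)
        first = np.array([tr.ground_truth.segments[0][0] for tr in trs])
        frac_folded = np.mean(first == "F_LF")
        assert frac_folded == pytest.approx(0.70, abs=0.03)


class TestIsotherm:
    def test_noiseless_equals_model(self):
        law = HillLaw(1.0, 1.8, 2.6)
        c = np.logspace(-1, 1, 8)
        iso = generate_isotherm(law, c, noise_sd=0.0)
        expected = [evaluate_rate_law(law, x) for x in c]
        np.testing.assert_allclose(iso.responses, expected)

    def test_reproducible_under_seed(self):
        law = HillLaw(1.0, 1.8, 2.6)
        c = np.logspace(-1, 1, 8)
        a = generate_isotherm(law, c, noise_sd=0.05, seed=9)
        b = generate_isotherm(law, c, noise_sd=0.05, seed=9)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_isotherm(ConstantLaw(1.0), [1.0, 2.0], 0.0)
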