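"""Idealization, dwell extraction, TDP, rate fits and mechanism calls."""

import itertools

import numpy as np
import pytest

from fretfold import kinetics
from fretfold.kinetics import (
    DwellRecord,
    IdealizedPath,
    build_tdp,
    classify_mechanism,
    competing_risks_rate,
    extract_dwells,
    fit_dwell_rate,
    fit_rate_vs_ligand,
    idealize,
    idealize_cohort,
    viterbi,
)
from fretfold.simulate import (
    ConstantLaw,
    HillLaw,
    KineticScheme,
    Photophysics,
    StateModel,
    generate_cohort,
)
from fretfold.traces import FretTrace, compute_fret


def _fret_trace(e, dt=0.05):
    e = np.asarray(e, float)
    return FretTrace(frame_dt=dt, e_app=e, valid=np.ones(e.size, bool),
                     valid_until=e.size)


def _brute_force_viterbi(e, model, transmat, startprob):
    """Exhaustive maximization over all state sequences (oracle)."""
    k = model.n_states
    mu = np.asarray(model.fret_means)
    sig = np.asarray(model.fret_sigmas)
    best, best_lp = None, -np.inf
    for seq in itertools.product(range(k), repeat=len(e)):
        lp = np.log(startprob[seq[0]])
        for t, s in enumerate(seq):
            lp += (-0.5 * np.log(2 * np.pi) - np.log(sig[s])
                   - 0.5 * ((e[t] - mu[s]) / sig[s]) ** 2)
            if t > 0:
                lp += np.log(transmat[seq[t - 1], s])
        if lp > best_lp:
            best, best_lp = seq, lp
    return np.array(best)


class TestIdealize:
    def test_noiseless_two_level_trace_exact(self, two_state_model):
        e = np.array([0.32] * 10 + [0.69] * 15 + [0.32] * 5)
        path = idealize(_fret_trace(e), two_state_model)
        expected = np.array([0] * 10 + [1] * 15 + [0] * 5)
        np.testing.assert_array_equal(path.frame_states, expected)

    @pytest.mark.parametrize("n_states", [2, 3])
    def test_viterbi_equals_exhaustive_enumeration(self, n_states):
        # 100 random short traces against the brute-force oracle
        if n_states == 2:
            model = StateModel(("A", "B"), (0.3, 0.7), (0.08, 0.08))
        else:
            model = StateModel(("A", "B", "C"), (0.3, 0.55, 0.75),
                               (0.08, 0.08, 0.08))
        rng = np.random.default_rng(42)
        k = model.n_states
        transmat = np.full((k, k), 0.1 / (k - 1))
        np.fill_diagonal(transmat, 0.9)
        startprob = np.full(k, 1.0 / k)
        n_cases = 50 if n_states == 3 else 50
        for _ in range(n_cases):
            t_len = int(rng.integers(2, 9 if n_states == 3 else 13))
            e = rng.uniform(0.1, 0.9, t_len)
            log_b = (-0.5 * np.log(2 * np.pi)
                     - np.log(np.asarray(model.fret_sigmas))
                     - 0.5 * ((e[:, None] - np.asarray(model.fret_means))
                              / np.asarray(model.fret_sigmas)) ** 2)
            ours = viterbi(log_b, transmat, startprob)
            oracle = _brute_force_viterbi(e, model, transmat, startprob)
            np.testing.assert_array_equal(ours, oracle)

    def test_short_trace_skipped(self, two_state_model):
        assert idealize(_fret_trace([0.3, 0.3, 0.3]), two_state_model) is None

    def test_close_states_misclassification_below_ten_percent(self):
        # F_LF (0.60) vs F_LB (0.69): a 0.09 gap at sigma = 0.05
        model = StateModel(("F_LF", "F_LB"), (0.60, 0.69), (0.05, 0.05))
        scheme = KineticScheme(("F_LF", "F_LB"),
                               np.array([[0, 0.25], [0.25, 0]]))
        cohort, _ = generate_cohort(
            scheme, model, 40, 0.05, 40.0,
            Photophysics(noise_sd=50.0, bleach_lifetime=None), seed=6)
        ftr = [compute_fret(t, detect_bleaching=False) for t in cohort]
        paths, _ = idealize_cohort(ftr, model, n_iter=10)
        err = n = 0
        for tr, p in zip(cohort, paths):
            truth = np.array([
                0 if tr.ground_truth.state_at((f + 0.5) * 0.05) == "F_LF" else 1
                for f in range(p.frame_states.size)])
            err += int(np.sum(truth != p.frame_states))
            n += truth.size
        assert err / n < 0.10


class TestDwells:
    def test_segment_extraction_and_censoring(self):
        path = IdealizedPath(("U", "F"), np.array([0] * 10 + [1] * 20 + [0] * 5),
                             frame_dt=0.05)
        dwells = extract_dwells([path])
        assert len(dwells) == 3
        f = dwells[1]
        assert (f.state, f.duration) == ("F", pytest.approx(1.0))
        assert not f.censored
        assert f.preceding == "U" and f.following == "U"
        assert dwells[0].censored_left and dwells[2].censored_right

    def test_single_segment_is_doubly_censored(self):
        path = IdealizedPath(("U", "F"), np.zeros(50, dtype=int), frame_dt=0.05)
        d = extract_dwells([path])[0]
        assert d.censored_left and d.censored_right

    def test_simulated_dwell_mean_matches_rate(self, two_state_model):
        k = 0.2
        scheme = KineticScheme(("U", "F_LB"), np.array([[0, k], [k, 0]]))
        cohort, _ = generate_cohort(
            scheme, two_state_model, 30, 0.05, 120.0,
            Photophysics(noise_sd=40.0, bleach_lifetime=None), seed=8)
        ftr = [compute_fret(t, detect_bleaching=False) for t in cohort]
        paths, _ = idealize_cohort(ftr, two_state_model, n_iter=10)
        durations = [d.duration for d in extract_dwells(paths)
                     if not d.censored]
        se = (1 / k) / np.sqrt(len(durations))
        assert np.mean(durations) == pytest.approx(1 / k, abs=3 * se)


class TestTdp:
    def test_two_state_alternation_two_bins(self):
        path = IdealizedPath(("U", "F"),
                             np.array([0, 0, 1, 1, 0, 1, 0, 0, 1]),
                             frame_dt=0.05)
        tdp = build_tdp([path], [0.32, 0.69])
        assert int((tdp.counts > 0).sum()) == 2

    def test_counting_identity(self, three_state_model):
        rates = np.array([[0, 0.5, 0.05], [0.35, 0, 0.2], [0.05, 0.3, 0]])
        scheme = KineticScheme(("U", "F_LF", "F_LB"), rates)
        cohort, _ = generate_cohort(
            scheme, three_state_model, 25, 0.05, 60.0,
            Photophysics(noise_sd=40.0, bleach_lifetime=None), seed=9)
        ftr = [compute_fret(t, detect_bleaching=False) for t in cohort]
        paths, _ = idealize_cohort(ftr, three_state_model, n_iter=5)
        tdp = build_tdp(paths, three_state_model)
        n_segments = sum(p.n_segments for p in paths)
        assert tdp.total == n_segments - len(paths)
        # self-transitions cannot occur: the diagonal stays empty
        assert np.all(np.diag(tdp.counts) == 0)

    def test_three_state_dynamics_populate_six_clusters(
            self, three_state_model):
        rates = np.array([[0, 0.5, 0.1], [0.35, 0, 0.2], [0.1, 0.3, 0]])
        scheme = KineticScheme(("U", "F_LF", "F_LB"), rates)
        cohort, _ = generate_cohort(
            scheme, three_state_model, 40, 0.05, 80.0,
            Photophysics(noise_sd=40.0, bleach_lifetime=None), seed=10)
        ftr = [compute_fret(t, detect_bleaching=False) for t in cohort]
        paths, _ = idealize_cohort(ftr, three_state_model, n_iter=5)
        tdp = build_tdp(paths, three_state_model)
        assert int((tdp.counts > 0).sum()) == 6


class TestDwellRateFit:
    def test_exponential_sample_recovered_by_both_methods(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(2.0, 10_000)
        for method in ("histogram_lsq", "mle"):
            fit = fit_dwell_rate(t, method=method)
            assert fit.rate == pytest.approx(0.5, abs=0.01), method

    def test_identical_dwells_mle_inverse_histogram_flagged(self):
        t = np.full(100, 4.0)
        mle = fit_dwell_rate(t, method="mle")
        assert mle.rate == pytest.approx(0.25)
        hist = fit_dwell_rate(t, method="histogram_lsq")
        assert any("poor" in f for f in hist.flags)

    def test_low_count_flagged(self):
        fit = fit_dwell_rate(np.random.default_rng(0).exponential(1.0, 10),
                             method="mle")
        assert any("low_confidence" in f for f in fit.flags)

    def test_slow_unfolding_recovered_at_200ms_frames(self):
        # F_LB -> F_LF regime: 0.036 1/s ground truth, 200 ms integration
        k = 0.036
        model = StateModel(("F_LF", "F_LB"), (0.60, 0.69), (0.05, 0.05))
        scheme = KineticScheme(("F_LF", "F_LB"),
                               np.array([[0, 0.1], [k, 0]]))
        cohort, _ = generate_cohort(
            scheme, model, 60, 0.2, 400.0,
            Photophysics(noise_sd=40.0, bleach_lifetime=None), seed=12)
        ftr = [compute_fret(t, detect_bleaching=False) for t in cohort]
        paths, _ = idealize_cohort(ftr, model, n_iter=10,
                                   max_baum_welch_traces=20)
        dwells = [d for d in extract_dwells(paths)
                  if d.state == "F_LB" and not d.censored]
        fit = fit_dwell_rate(dwells, method="histogram_lsq", frame_dt=0.2)
        assert fit.rate == pytest.approx(k, rel=0.15)

    def test_censored_dwells_bias_the_rate(self):
        # a censored record observes only part of its dwell; mixing such
        # truncated observations into the fit biases the dwell time low and
        # the rate away from truth, while the uncensored subset is clean
        k = 0.2
        rng = np.random.default_rng(14)
        complete = rng.exponential(1 / k, 4000)
        in_progress = rng.exponential(1 / k, 1000) * rng.uniform(0, 1, 1000)
        k_unc = fit_dwell_rate(complete, method="mle").rate
        k_all = fit_dwell_rate(np.concatenate([complete, in_progress]),
                               method="mle").rate
        assert abs(k_unc - k) < abs(k_all - k)
        assert k_all > k  # truncated observations are short -> rate too high


class TestRateVsLigand:
    def test_constant_rates_fit_flat_line(self):
        fit = fit_rate_vs_ligand([75, 150, 300, 600], [0.18] * 4,
                                 model="constant_line")
        assert fit.params["k_mean"] == pytest.approx(0.18)
        assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_hill_round_trip(self):
        c = np.array([10, 30, 80, 200, 500, 1500.0])
        k = 0.27 * c / (80.0 + c)
        fit = fit_rate_vs_ligand(c, k, model="hill")
        assert fit.params["k_max"] == pytest.approx(0.27, rel=1e-4)
        assert fit.params["K_D"] == pytest.approx(80.0, rel=1e-4)
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-4)

    def test_noisy_hill_ladder_median_kd_within_twenty_percent(self):
        c = np.array([75, 150, 250, 400, 600, 1000.0])
        law = HillLaw(1.22, 310.0, 3.1)
        truth = np.array([law.k_max * (x / law.K_D) ** law.n
                          / (1 + (x / law.K_D) ** law.n) for x in c])
        kds = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            noisy = truth * (1 + 0.1 * rng.standard_normal(c.size))
            kds.append(fit_rate_vs_ligand(c, noisy, model="hill").params["K_D"])
        assert np.median(kds) == pytest.approx(310.0, rel=0.20)


class TestCompetingRisks:
    def test_branching_fraction_scales_exit_rate(self):
        dwells = (
            [DwellRecord("F_LF", 2.0, "U", "F_LB", False, False)] * 30
            + [DwellRecord("F_LF", 2.0, "U", "U", False, False)] * 10
        )
        total = fit_dwell_rate([d for d in dwells], method="mle")
        fit = competing_risks_rate(dwells, "F_LF", "F_LB", method="mle")
        assert fit.rate == pytest.approx(total.rate * 0.75)


class TestMechanism:
    def test_rising_dock_flat_undock_is_induced_fit(self):
        c = np.array([25, 75, 150, 300, 600, 1000.0])
        dock = 1.22 * c**3.1 / (310.0**3.1 + c**3.1)
        rng = np.random.default_rng(1)
        undock = 0.18 + rng.normal(0, 0.005, c.size)
        report = classify_mechanism(c, dock, c, undock)
        assert report.label == "induced-fit"

    def test_flat_dock_falling_undock_is_conformational_selection(self):
        c = np.array([25, 75, 150, 300, 600, 1000.0])
        rng = np.random.default_rng(2)
        dock = 0.2 + rng.normal(0, 0.003, c.size)
        undock = 0.5 / (1 + c / 100.0)
        report = classify_mechanism(c, dock, c, undock)
        assert report.label == "conformational-selection"

    def test_both_dependent_is_mixed(self):
        c = np.array([25, 75, 150, 300, 600, 1000.0])
        dock = 1.0 * c / (100.0 + c)
        undock = 0.5 / (1 + c / 100.0)
        report = classify_mechanism(c, dock, c, undock)
        assert report.label == "mixed"

    def test_too_few_points_undetermined(self):
        report = classify_mechanism([1, 2], [0.1, 0.2], [1, 2], [0.1, 0.1])
        assert report.label == "undetermined"
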