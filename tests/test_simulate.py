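import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.stats.diagnostic import acorr_ljungbox

from cnqc.cbs import CBSConfig, cbs_profile
from cnqc.simulate import (
    SimProfileSpec,
    apply_median_filter,
    apply_wave_artefact,
    segment_recovery_stats,
    simulate_cohort,
    simulate_reliable,
)
from cnqc.stepfit import StepFitConfig, step_fit


class TestSimulateReliable:
    def test_construction_contract(self):
        spec = SimProfileSpec(n=10_000, n_cna_segments=12, seed=4)
        prof, truth = simulate_reliable(spec)
        assert prof.n == 10_000
        assert int(np.sum(truth.levels != 0.0)) == 12
        assert truth.changepoints[0] == 0 and truth.changepoints[-1] == 10_000

    def test_same_seed_is_bit_identical(self):
        spec = SimProfileSpec(seed=9)
        p1, t1 = simulate_reliable(spec)
        p2, t2 = simulate_reliable(spec)
        assert np.array_equal(p1.value, p2.value)
        assert np.array_equal(t1.changepoints, t2.changepoints)

    def test_near_noiseless_stepfit_recovers_true_boundaries(self):
        spec = SimProfileSpec(n=4000, n_chromosomes=1, n_cna_segments=6, noise_sd=1e-6, seed=12)
        prof, truth = simulate_reliable(spec)
        res = step_fit(prof.value, StepFitConfig(K=60))
        true_cps = set(truth.changepoints.tolist())
        # the first selections are all genuine boundaries
        for c in res.selected[:6]:
            assert c in true_cps

    def test_cna_levels_come_from_the_configured_set(self):
        spec = SimProfileSpec(n_cna_segments=15, seed=3)
        _, truth = simulate_reliable(spec)
        assert set(np.unique(truth.levels)) <= {0.0, -1.0, -0.58, 0.58, 1.0}

    def test_residuals_behave_like_iid_noise(self):
        """Group-A residuals after subtracting the true levels pass a
        Ljung-Box whiteness check in the vast majority of runs."""
        fails = 0
        runs = 40
        for seed in range(runs):
            spec = SimProfileSpec(n=4000, n_chromosomes=8, seed=7000 + seed)
            prof, truth = simulate_reliable(spec)
            mu = np.repeat(truth.levels, truth.counts)
            resid = prof.value - mu
            p = acorr_ljungbox(resid, lags=[10]).iloc[0]["lb_pvalue"]
            if p < 0.01:
                fails += 1
        assert fails <= runs // 10


class TestWaveArtefact:
    def test_zero_wave_sd_is_identity(self):
        spec = SimProfileSpec(seed=5, wave_sd=0.0)
        prof, _ = simulate_reliable(spec)
        out = apply_wave_artefact(prof, spec)
        assert np.array_equal(out.value, prof.value)

    def test_strong_wave_is_heavily_autocorrelated(self):
        spec = SimProfileSpec(seed=6, wave_strength=0.999, wave_sd=0.5 * np.sqrt(1 - 0.999**2))
        prof, _ = simulate_reliable(spec)
        out = apply_wave_artefact(prof, spec)
        wave = out.value - prof.value
        r = np.corrcoef(wave[:-1], wave[1:])[0, 1]
        assert r >= 0.99

    def test_positions_and_length_unchanged(self):
        spec = SimProfileSpec(seed=8)
        prof, _ = simulate_reliable(spec)
        out = apply_wave_artefact(prof, spec)
        assert out.n == prof.n
        assert np.array_equal(out.position, prof.position)
        assert list(out.chromosome) == list(prof.chromosome)

    def test_sinusoid_wave_model_available(self):
        spec = SimProfileSpec(seed=8, wave_model="sinusoid")
        prof, _ = simulate_reliable(spec)
        out = apply_wave_artefact(prof, spec)
        assert np.std(out.value - prof.value) > 0.1


class TestMedianFilter:
    def test_window_one_is_identity(self):
        prof, _ = simulate_reliable(SimProfileSpec(seed=2))
        out = apply_median_filter(prof, 1)
        assert np.array_equal(out.value, prof.value)

    def test_constant_input_unchanged(self):
        prof, _ = simulate_reliable(SimProfileSpec(n=500, n_cna_segments=0, seed=2))
        flat = dataclasses.replace(prof)
        flat.value[:] = 0.25
        out = apply_median_filter(flat, 31)
        assert np.allclose(out.value, 0.25)

    def test_even_window_rejected(self):
        prof, _ = simulate_reliable(SimProfileSpec(n=500, seed=2))
        with pytest.raises(ValueError, match="odd"):
            apply_median_filter(prof, 10)

    def test_filtering_hyper_segments_cbs(self):
        spec = SimProfileSpec(seed=44)
        prof, _ = simulate_reliable(spec)
        cfg = CBSConfig(n_permutations=500, rng_seed=1)
        _, v_before = cbs_profile(prof, cfg)
        _, v_after = cbs_profile(apply_median_filter(prof, spec.medfilter_window), cfg)
        assert v_after > v_before


class TestCohort:
    def test_bookkeeping(self):
        cohort = simulate_cohort(2, spec=SimProfileSpec(n=2000, seed=1))
        assert len(cohort) == 10
        assert {s.group for s in cohort} == {"A", "B", "C", "flat", "highDLRS"}
        for s in cohort:
            expected = "reliable" if s.group in ("A", "flat") else "unreliable"
            assert s.label == expected

    def test_group_a_counts_within_sampling_range(self):
        cohort = simulate_cohort(5, groups=("A",), spec=SimProfileSpec(seed=2))
        for s in cohort:
            assert 5 <= s.n_cna <= 40

    def test_empty_group_set_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(3, groups=())

    def test_deterministic_per_master_seed(self):
        a = simulate_cohort(2, groups=("A", "B"), spec=SimProfileSpec(n=1000, seed=5))
        b = simulate_cohort(2, groups=("A", "B"), spec=SimProfileSpec(n=1000, seed=5))
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.profile.value, s2.profile.value)


class TestRecoveryStats:
    def test_perfect_recovery(self):
        t = [10, 20, 30, 40, 50]
        rho, w, b = segment_recovery_stats(t, t)
        assert rho == pytest.approx(1.0)
        assert w == pytest.approx(1.0, abs=1e-8)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_rho_matches_rank_oracle(self):
        t = [3, 1, 4, 1.5, 5, 9, 2, 6]
        e = [2, 1, 5, 3, 4, 10, 2.5, 7]
        # brute-force rank correlation: Pearson on ranks
        from scipy.stats import rankdata

        rt, re = rankdata(t), rankdata(e)
        expected = np.corrcoef(rt, re)[0, 1]
        rho, _, _ = segment_recovery_stats(t, e)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_huber_slope_resists_gross_outlier(self):
        t = np.arange(1.0, 21.0)
        e = t.copy()
        e[10] += 200.0
        _, w, _ = segment_recovery_stats(t, e)
        ols = sm.OLS(e, sm.add_constant(t)).fit().params[1]
        assert abs(w - 1.0) < abs(ols - 1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            segment_recovery_stats([5, 5, 5], [1, 2, 3])
        with pytest.raises(ValueError):
            segment_recovery_stats([1, 2], [1, 2])
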