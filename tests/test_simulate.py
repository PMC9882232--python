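import numpy as np
import pytest

from neqmoments import closed_forms as cf
from neqmoments import demography as dem
from neqmoments import simulate as sim
from neqmoments import stats as st
from neqmoments import make_params, ParameterError
from neqmoments.simulate import expected_freq_after_selection


class TestSelection:
    def test_boundaries_are_fixed_points(self):
        for s_hom, s_het in ((-0.2, -0.1), (0.5, 0.2), (0.0, 0.0)):
            assert expected_freq_after_selection(0.0, s_hom, s_het) == 0.0
            assert expected_freq_after_selection(1.0, s_hom, s_het) == 1.0

    def test_diploid_value(self):
        assert expected_freq_after_selection(0.5, -0.2, -0.1) == \
            pytest.approx(0.425 / 0.9, rel=1e-12)

    def test_deleterious_never_increases(self):
        p = np.linspace(0.01, 0.99, 50)
        pbar = expected_freq_after_selection(p, -0.2, -0.1)
        assert np.all(pbar < p)

    @pytest.mark.parametrize("s", [1e-4, 1e-3])
    def test_weak_selection_matches_langevin_drift(self, s):
        """For additive effects, (pbar - p) ~ -s p (1-p) to first order."""
        p = np.linspace(0.05, 0.95, 19)
        delta = expected_freq_after_selection(p, -2 * s, -s) - p
        np.testing.assert_allclose(delta, -s * p * (1 - p), rtol=0.01)

    def test_lethal_rejected(self):
        with pytest.raises(ParameterError):
            expected_freq_after_selection(0.5, -1.0, -0.5)


def _config(**kw):
    defaults = dict(L=1000, generations=50,
                    params=make_params(s=1e-1, mu=1e-6, mu_b=1e-8, p0=5e-4),
                    demography=dem.constant(1e3), init_count=1, printgen=10,
                    seed=0)
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestRun:
    def test_reproducible_and_seed_sensitive(self):
        r1 = sim.run(_config())
        r2 = sim.run(_config())
        r3 = sim.run(_config(seed=1))
        assert np.array_equal(r1.noncentral, r2.noncentral)
        assert not np.array_equal(r1.noncentral, r3.noncentral)

    def test_initial_moments_are_exact(self):
        res = sim.run(_config(init_count=7))
        assert res.times[0] == 0.0
        assert res.noncentral[0, 0] == pytest.approx(7 / 2e3, rel=1e-14)
        np.testing.assert_allclose(res.central[0], 0.0, atol=1e-30)
        np.testing.assert_allclose(res.cumulants[0, 1:], 0.0, atol=1e-18)

    def test_absorbing_state_without_mutation(self):
        p = make_params(s=1e-12, mu=0.0, mu_b=0.0, p0=0.0)
        cfg = _config(params=p, init_count=0, generations=30)
        res = sim.run(cfg)
        assert np.all(res.noncentral == 0.0)

    def test_reporting_cadence(self):
        res = sim.run(_config(generations=50, printgen=10))
        assert list(res.times[:11]) == [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        assert list(res.times[11:]) == [20, 30, 40, 50]

    def test_cumulant_consistency_with_noncentral(self):
        """Cumulants recomputed from the recorded non-central moments
        match the recorded cumulants at every time point."""
        res = sim.run(_config(generations=200, L=5000))
        k = st.cumulants_from_noncentral(res.noncentral[:, :4])
        np.testing.assert_allclose(k, res.cumulants[:, :4], atol=1e-15)

    def test_frequencies_in_range_and_sizes_rounded(self):
        cfg = _config(demography=dem.exponential(997.4, 2e-3), generations=100)
        res = sim.run(cfg)
        assert np.all(res.noncentral[:, 0] >= 0) and np.all(res.noncentral[:, 0] <= 1)
        assert np.all(res.pop_size == np.floor(997.4 * np.exp(2e-3 * res.times) + 0.5))

    def test_neutral_drift_mean_is_martingale(self):
        p = make_params(s=1e-15, mu=0.0, mu_b=0.0, p0=0.05)
        cfg = _config(params=p, L=10000, init_count=100, generations=200,
                      demography=dem.constant(1e3), seed=7)
        res = sim.run(cfg)
        p0 = 100 / 2e3
        se = np.sqrt(p0 * (1 - p0) * (res.times[-1] / 2e3) / 10000)
        assert abs(res.noncentral[-1, 0] - p0) < 4 * se

    def test_mean_tracks_deterministic_trajectory(self):
        """Recorded m1 follows p0 e^{-s't} + lambda'(1-e^{-s't}) within
        Monte-Carlo noise (constant N = 1e3, strong selection)."""
        p = make_params(s=1e-1, mu=1e-6, mu_b=1e-8, p0=1 / 2e3)
        cfg = _config(params=p, L=20000, generations=400, seed=11)
        res = sim.run(cfg)
        ref = cf.mean_constant(p, res.times).values
        se = np.sqrt(np.maximum(res.central[:, 0], 1e-30) / 20000)
        z = (res.noncentral[:, 0] - ref) / np.where(se > 0, se, np.inf)
        assert np.mean(np.abs(z) <= 3) >= 0.95
        assert np.all(np.abs(z) <= 5)

    def test_unfixation_through_back_mutation(self):
        p = make_params(s=1e-12, mu=0.0, mu_b=0.05, p0=0.0)
        cfg = _config(params=p, L=200, demography=dem.constant(100.0),
                      init_count=200, generations=30)
        res = sim.run(cfg)
        assert res.noncentral[0, 0] == 1.0
        assert res.noncentral[-1, 0] < 1.0

    def test_config_errors(self):
        with pytest.raises(ParameterError):
            sim.run(_config(init_count=100000))
        with pytest.raises(ParameterError):
            sim.run(_config(L=0))
        shrink = dem.exponential(10.0, -0.5)
        with pytest.raises(ParameterError):
            sim.run(_config(demography=shrink, generations=50))

    def test_burnin_equilibrates_before_recording(self):
        p = make_params(s=1e-1, mu=1e-4, mu_b=1e-6, p0=0.0)
        cfg = _config(params=p, L=5000, init_count=0, burnin=300,
                      generations=20, seed=3)
        res = sim.run(cfg)
        # after burn-in the mean starts near mutation-selection balance
        assert res.noncentral[0, 0] == pytest.approx(p.lambda_prime, rel=0.3)

    def test_oscillating_late_time_variance(self):
        """Time-averaged late-time variance matches the harmonic-mean
        effective-size prediction lambda'/(4 Nbar_osc s')."""
        nmax, nmin, tau = 1e4, 1e3, 1e3
        p = make_params(s=1e-1, mu=1e-6, mu_b=1e-8, p0=1 / 2e4)
        cfg = _config(params=p, L=20000, demography=dem.oscillating(nmax, nmin, tau),
                      init_count=1, generations=3000, seed=5, n_blocks=50)
        res = sim.run(cfg)
        late = res.times >= 1000
        nbar = dem.effective_size_osc(nmax, nmin)
        expected = p.lambda_prime / (4 * nbar * p.s_prime)
        # discrete-generation factor: the stationary variance of the
        # per-generation recursion is 1/(1 - s'/2) times the
        # continuous-time value (geometric vs exponential decay); at
        # s' = 0.1 this is a +5% offset, well resolved at L = 2e4
        expected /= 1.0 - p.s_prime / 2.0
        # SE of the time-average from across-block scatter
        kb = st.cumulants_from_noncentral(res.block_noncentral)  # (T,B,4)
        block_avg = kb[late, :, 1].mean(axis=0)                  # (B,)
        se = block_avg.std(ddof=1) / np.sqrt(block_avg.size)
        assert abs(block_avg.mean() - expected) < 3 * se
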