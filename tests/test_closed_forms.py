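import numpy as np
import pytest

from neqmoments import closed_forms as cf
from neqmoments import demography as dem
from neqmoments import diagrams as dg
from neqmoments import make_params


class TestConstantSize:
    def test_mean_endpoints(self, pg_round):
        t = np.array([0.0, 1e6])
        tr = cf.mean_constant(pg_round, t)
        assert tr.values[0] == pytest.approx(pg_round.p0)
        assert tr.values[1] == pytest.approx(pg_round.lambda_prime, rel=1e-9)

    def test_mean_value(self, pg_round):
        # s' = 0.01, lambda' = 1e-4, p0 = 5e-5, t = 100
        tr = cf.mean_constant(pg_round, np.array([100.0]))
        assert tr.values[0] == pytest.approx(8.1606e-5, rel=1e-4)

    def test_variance_value(self, pg_round):
        tr = cf.variance_constant(pg_round, 1e4, np.array([100.0]))
        assert tr.values[0] == pytest.approx(1.580e-7, rel=1e-3)

    def test_cumulants_vanish_at_zero(self, pg_round):
        t = np.array([0.0])
        for fn in (lambda: cf.variance_constant(pg_round, 1e4, t),
                   lambda: cf.kappa3_constant(pg_round, 1e4, t),
                   lambda: cf.kappa4_constant(pg_round, 1e4, t)):
            assert fn().values[0] == 0.0

    def test_asymptotes(self, pg_round):
        t = np.array([1e7])
        lp, g = pg_round.lambda_prime, pg_round.gamma_prime(1e4)
        assert cf.variance_constant(pg_round, 1e4, t).values[0] == \
            pytest.approx(lp / (2 * g), rel=1e-9)
        assert cf.kappa3_constant(pg_round, 1e4, t).values[0] == \
            pytest.approx(lp / (2 * g ** 2), rel=1e-9)
        assert cf.kappa4_constant(pg_round, 1e4, t).values[0] == \
            pytest.approx(3 * lp / (4 * g ** 3), rel=1e-9)

    def test_d8_is_two_thirds_of_mutational_kappa4(self, pg_round, const_demog):
        """The chain diagrams alone asymptote to lambda'/2gamma'^3, i.e.
        two thirds of the full mutational term."""
        t = np.array([2000.0])
        lp, g = pg_round.lambda_prime, pg_round.gamma_prime(1e4)
        v = dg.evaluate_diagram_exact("D8R", pg_round, const_demog, t).values[0]
        assert v == pytest.approx(lp / (2 * g ** 3), rel=1e-3)

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_noncentral_at_zero_and_equilibrium(self, order):
        p = make_params(s=1e-2, mu=1e-8, mu_b=0.0, p0=5e-5)
        N = 1e4
        tr0 = cf.noncentral_moments_constant(p, N, np.array([0.0]), order)
        assert tr0.values[0] == pytest.approx(p.p0 ** order, rel=1e-12)
        tr = cf.noncentral_moments_constant(p, N, np.array([1e7]), order)
        if order == 2:   # homozygosity at mutation-selection-drift balance
            assert tr.values[0] == pytest.approx(p.mu / (4 * N * p.s ** 2), rel=1e-2)
        if order == 4:
            assert tr.values[0] == pytest.approx(
                3 * p.mu / (4 * (2 * N * p.s) ** 3 * p.s), rel=1e-2)

    def test_three_vertex_signflip_threshold(self):
        """The late-time three-vertex variance changes sign at
        gamma' = 1/(2(1-lambda')), i.e. 1/2 in the weak-mutation limit."""
        p = make_params(s=1e-2, mu=1e-8, mu_b=0.0, p0=1e-5)
        gstar = cf.variance_signflip_gamma(p)
        assert gstar == pytest.approx(0.5, rel=1e-5)
        for factor, sign in ((1.01, 1.0), (0.99, -1.0)):
            N = factor * gstar / (2 * p.s_prime)
            assert np.sign(cf.three_vertex_variance_asymptote(p, N)) == sign
        strong_mut = make_params(s=1e-2, mu=5e-3, mu_b=0.0, p0=1e-5)
        lp = strong_mut.lambda_prime
        assert cf.variance_signflip_gamma(strong_mut) == \
            pytest.approx(1 / (2 * (1 - lp)), rel=1e-12)


class TestExponential:
    def test_gamma_zero_reduces_to_constant(self, pg_weak, resolved_grid):
        N = 1e4
        refs = {2: cf.variance_constant(pg_weak, N, resolved_grid).values,
                3: cf.kappa3_constant(pg_weak, N, resolved_grid).values,
                4: cf.kappa4_constant(pg_weak, N, resolved_grid).values}
        for order, ref in refs.items():
            red = cf.kappas_exponential(pg_weak, N, 0.0, resolved_grid, order).values
            np.testing.assert_allclose(red, ref, rtol=1e-10)

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_vanishes_at_zero_and_late_times(self, pg_weak, order):
        t = np.geomspace(1.0, 2e4, 60)
        tr = cf.kappas_exponential(pg_weak, 1e3, 1e-3,
                                   np.concatenate([[0.0], t]), order)
        assert tr.values[0] == pytest.approx(0.0, abs=1e-18)
        # the cumulants vanish as the population grows without bound
        assert abs(tr.values[-1]) < 1e-3 * abs(tr.values).max()

    def test_printed_variance_transcription(self, pg_weak):
        """The kappa_2 expression is the literal transcription; pin one
        value against the exact diagram evaluation."""
        d = dem.exponential(1e3, 1e-3)
        t = np.geomspace(1.0, 2000.0, 12)
        exact = sum(dg.evaluate_diagram_exact(x, pg_weak, d, t).values
                    for x in ("D4L", "D4R"))
        trans = cf.kappas_exponential(pg_weak, 1e3, 1e-3, t, 2).values
        np.testing.assert_allclose(trans, exact, rtol=1e-10)

    def test_printed_kappa3_transcription(self, pg_weak):
        d = dem.exponential(1e3, 1e-3)
        t = np.geomspace(1.0, 2000.0, 12)
        exact = sum(dg.evaluate_diagram_exact(x, pg_weak, d, t).values
                    for x in ("D7L", "D7R"))
        trans = cf.kappas_exponential(pg_weak, 1e3, 1e-3, t, 3).values
        np.testing.assert_allclose(trans, exact, rtol=1e-10)

    def test_pole_guard_continuity(self, pg_weak):
        """Evaluation at Gamma exactly on the 2s' pole agrees with
        evaluation just off it."""
        t = np.geomspace(1.0, 300.0, 8)
        on = cf.kappas_exponential(pg_weak, 1e3, 2 * pg_weak.s_prime, t, 2).values
        off = cf.kappas_exponential(pg_weak, 1e3,
                                    2 * pg_weak.s_prime * (1 + 1e-7), t, 2).values
        np.testing.assert_allclose(on, off, rtol=1e-4)
        assert np.all(np.isfinite(on))


class TestBottleneck:
    def test_degenerate_reduces_to_constant(self, pg_weak, resolved_grid):
        N = 1e4
        red2 = cf.kappa2_bottleneck(pg_weak, N, N, 1e3, 1e3, resolved_grid).values
        np.testing.assert_allclose(red2, cf.variance_constant(pg_weak, N, resolved_grid).values,
                                   rtol=1e-10)
        red3 = cf.kappa3_bottleneck(pg_weak, N, N, 1e3, 1e3, resolved_grid).values
        np.testing.assert_allclose(red3, cf.kappa3_constant(pg_weak, N, resolved_grid).values,
                                   rtol=1e-10)

    def test_constant_before_onset_and_requilibration(self, pg_weak):
        N0, Nb, Ti, Tb = 1e4, 1e3, 1e3, 1e3
        pre = np.geomspace(1.0, Ti, 20)
        k2 = cf.kappa2_bottleneck(pg_weak, N0, Nb, Ti, Tb, pre).values
        np.testing.assert_allclose(k2, cf.variance_constant(pg_weak, N0, pre).values,
                                   rtol=1e-12)
        late = np.array([5e4])
        lp, g0 = pg_weak.lambda_prime, pg_weak.gamma_prime(N0)
        assert cf.kappa2_bottleneck(pg_weak, N0, Nb, Ti, Tb, late).values[0] == \
            pytest.approx(lp / (2 * g0), rel=1e-6)

    def test_variance_rises_during_bottleneck(self, pg_weak):
        k2 = cf.kappa2_bottleneck(pg_weak, 1e4, 1e3, 1e3, 1e3,
                                  np.array([999.0, 1500.0, 1999.0])).values
        assert k2[1] > k2[0] and k2[2] > k2[1]


class TestOscillating:
    def test_degenerate_reduces_to_constant(self, pg_weak, resolved_grid):
        N = 1e4
        red = cf.kappa2_oscillating(pg_weak, N, N, 1e3, resolved_grid).values
        np.testing.assert_allclose(red, cf.variance_constant(pg_weak, N, resolved_grid).values,
                                   rtol=1e-10)

    def test_late_time_form_agrees(self, pg_weak):
        """The full variance converges to the asymptotic oscillation."""
        t = np.linspace(50.0 / pg_weak.s_prime, 50.0 / pg_weak.s_prime + 2e3, 64)
        full = cf.kappa2_oscillating(pg_weak, 1e4, 1e3, 1e3, t).values
        asym = cf.kappa2_oscillating_asymptotic(pg_weak, 1e4, 1e3, 1e3, t).values
        np.testing.assert_allclose(full, asym, rtol=1e-4)

    def test_mean_of_asymptotic_is_harmonic_mean_variance(self, pg_weak):
        """Time-averaged late-time variance equals that of a constant
        population at the harmonic-mean effective size."""
        nmax, nmin, tau = 1e4, 1e3, 1e3
        t = np.linspace(1e5, 1e5 + tau, 20001)[:-1]
        asym = cf.kappa2_oscillating_asymptotic(pg_weak, nmax, nmin, tau, t).values
        nbar = dem.effective_size_osc(nmax, nmin)
        expected = pg_weak.lambda_prime / (2 * pg_weak.gamma_prime(nbar))
        assert np.mean(asym) == pytest.approx(expected, rel=1e-6)


class TestStandardized:
    def test_equilibrium_shape_statistics(self):
        """K3 -> 1/sqrt(N mu), K4 -> 3/(2 N mu), xi -> 1: selection drops
        out of the standardized shape at strong-selection equilibrium."""
        for N, mu, s in ((1e4, 1e-8, 1e-2), (1e3, 1e-6, 1e-1), (1e5, 1e-7, 1e-3)):
            p = make_params(s=s, mu=mu, mu_b=mu / 100, p0=1 / (2 * N))
            asym = cf.asymptotic_standardized(p, N)
            assert asym["K3"] == pytest.approx(1 / np.sqrt(N * mu), rel=1e-9)
            assert asym["K4"] == pytest.approx(3 / (2 * N * mu), rel=1e-9)
            assert asym["xi"] == pytest.approx(1.0, rel=1e-12)

    def test_set_handles_degenerate_start(self, pg_weak, const_demog):
        t = np.array([0.0, 10.0, 3000.0])
        ks = cf.analytic_cumulants(pg_weak, const_demog, t)
        cs = cf.standardized_set(*(ks[n] for n in (1, 2, 3, 4)))
        assert np.isnan(cs.K3[0]) and np.isnan(cs.K4[0]) and np.isnan(cs.xi[0])
        assert cs.xi[-1] == pytest.approx(1.0, rel=1e-3)

    def test_grid_mismatch_rejected(self, pg_weak, const_demog):
        ks = cf.analytic_cumulants(pg_weak, const_demog, np.array([0.0, 1.0]))
        other = cf.mean_constant(pg_weak, np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            cf.standardized_set(other, ks[2], ks[3], ks[4])
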