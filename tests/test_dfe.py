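import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gamma as sgamma

from haplodfe.demography import DemographicModel, SampleConfig
from haplodfe.ibs import IBSData, WindowScheme
from haplodfe import dfe
from haplodfe import likelihood as lik


class TestDiscretizedGamma:
    @given(st.floats(0.05, 5.0), st.floats(0.5, 3000.0), st.integers(2, 250))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_normalization_exact(self, alpha, beta, tau):
        pmf = dfe.discretized_gamma(alpha, beta, tau)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pmf >= 0)

    def test_zero_bin_is_cdf_at_half(self):
        pmf = dfe.discretized_gamma(0.3, 100.0, 50)
        assert pmf[0] == pytest.approx(sgamma.cdf(0.5, a=0.3, scale=100.0))

    def test_values_match_numerical_pdf_integration(self):
        """Independent oracle: integrate the gamma density numerically over
        each unit bin (shape/scale from a published human DFE fit)."""
        alpha, beta, tau = 0.184, 1599.313, 200
        pmf = dfe.discretized_gamma(alpha, beta, tau)
        for g in (1, 2, 10, 50, 150):
            xs = np.linspace(g - 0.5, g + 0.5, 4001)
            dens = sgamma.pdf(xs, a=alpha, scale=beta)
            assert pmf[g] == pytest.approx(np.trapezoid(dens, xs), rel=1e-5)
        # the collapsed tail holds everything above tau - 0.5
        assert pmf[tau] == pytest.approx(
            sgamma.sf(tau - 0.5, a=alpha, scale=beta))

    def test_raising_tau_never_raises_lower_entries(self):
        a, b = 0.3, 80.0
        small = dfe.discretized_gamma(a, b, 30)
        large = dfe.discretized_gamma(a, b, 60)
        assert np.all(large[:31] <= small + 1e-15)
        assert np.allclose(large[:30], small[:30])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dfe.discretized_gamma(-1.0, 10.0, 5)


def separated_table(tau, m=4, spread=0.9):
    """Integer-grid table whose rows drift smoothly with 4Ns."""
    grid = np.arange(0, tau + 1, dtype=float)
    base = np.linspace(0.6, 0.6 - spread * 0.5, tau + 1)
    pmfs = np.empty((tau + 1, m))
    for i, b in enumerate(base):
        rest = (1 - b) / (m - 1)
        pmfs[i] = [b] + [rest] * (m - 1)
        pmfs[i, -1] += 0.0
    return lik.LikelihoodTable(grid, pmfs, np.full(tau + 1, 1e6),
                               WindowScheme.equidistant(m, 10_000.0),
                               {"K": 1000, "reps": 100, "n": 10})


class TestEstimateDfef:
    def test_point_mass_limit_reduces_to_fixed_gamma_composite(self):
        tau = 20
        tab = separated_table(tau)
        g_star = 7
        # a near-degenerate gamma at g_star
        alpha, beta = 1e4, g_star / 1e4
        pmf = dfe.discretized_gamma(alpha, beta, tau)
        assert pmf[g_star] > 0.999
        counts = np.array([40, 20, 20, 20])
        mix = pmf @ tab.pmfs
        direct = counts @ np.log(tab.pmfs[g_star])
        via_mix = counts @ np.log(mix)
        assert via_mix == pytest.approx(direct, abs=0.02)

    def test_grid_search_recovers_generating_mixture(self):
        tau = 30
        tab = separated_table(tau)
        rng = np.random.default_rng(1)
        true = dfe.DFEfParams(0.4, 40.0, tau)
        mix = true.pmf @ tab.pmfs
        counts = rng.multinomial(60_000, mix)
        params, surface = dfe.estimate_dfef(
            counts, tab, tau, alpha_grid=(0.1, 0.2, 0.4, 0.8),
            beta_grid=(5.0, 10.0, 20.0, 40.0, 80.0, 160.0), ess_threshold=0)
        # with a table whose rows vary linearly in 4Ns only the mean of the
        # mixing distribution is identified: shape and scale trade off, but
        # their product (the mean, after tail collapse) is pinned down
        assert params.mean == pytest.approx(true.mean, rel=0.15)

    def test_missing_integer_coverage_raises(self):
        tab = separated_table(10)
        with pytest.raises(ValueError):
            dfe.estimate_dfef(np.array([5, 5, 5, 5]), tab, tau=20)


class TestBayesConversion:
    def test_equal_frequency_probabilities_are_identity(self):
        fc = dfe.FrequencyConditionals(
            p_f=0.02, p_f_given_s=np.array([0.02, 0.02, 0.02]),
            p_s_given_f=np.array([0.5, 0.3, 0.2]),
            n_total=100, n_f=2, n_sj=np.array([1, 1, 0]),
            n_sj_f=np.array([1, 1, 0]))
        out = dfe.convert_dfef_to_dfe(np.array([0.5, 0.3, 0.2]), fc)
        assert np.allclose(out.probabilities, [0.5, 0.3, 0.2])
        assert out.renormalization_shift < 1e-12

    def test_count_identity_is_exact_on_shared_counts(self):
        """Plugging the three count-derived probabilities into the Bayes
        formula returns exactly n_sj / n_total."""
        n_total = 10_000
        n_sj = np.array([6000, 3000, 1000])
        n_sj_f = np.array([120, 30, 5])
        n_f = n_sj_f.sum()
        p_s_given_f = n_sj_f / n_f
        p_f = n_f / n_total
        p_f_given_s = n_sj_f / n_sj
        raw = p_s_given_f * p_f / p_f_given_s
        assert np.allclose(raw, n_sj / n_total)
        fc = dfe.FrequencyConditionals(p_f, p_f_given_s, p_s_given_f,
                                       n_total, n_f, n_sj, n_sj_f)
        out = dfe.convert_dfef_to_dfe(p_s_given_f, fc)
        assert np.allclose(out.probabilities, n_sj / n_total)

    def test_zero_denominator_with_mass_raises(self):
        fc = dfe.FrequencyConditionals(
            p_f=0.1, p_f_given_s=np.array([0.1, 0.0]),
            p_s_given_f=np.array([0.5, 0.5]),
            n_total=10, n_f=1, n_sj=np.array([5, 5]),
            n_sj_f=np.array([1, 0]))
        with pytest.raises(ZeroDivisionError):
            dfe.convert_dfef_to_dfe(np.array([0.5, 0.5]), fc)


class TestFrequencyConditionals:
    def test_point_neutral_dfe_single_bin(self):
        """With a point mass at s=0 and one bin, P(f|D) == P(f|s1,D) up to
        shared Monte-Carlo draws."""
        dem = DemographicModel.constant(150)
        sc = SampleConfig(S=300, f=0.02, n=2)
        sampler = lambda rng, k: np.zeros(k)
        fc = dfe.estimate_frequency_conditionals(
            sampler, dem, sc, b=1, theta=30.0, n_sims=3, seed=2,
            horizon_factor=6)
        assert fc.p_s_given_f == pytest.approx([1.0])
        assert fc.p_f > 0 and fc.p_f_given_s[0] > 0
        rel = abs(fc.p_f - fc.p_f_given_s[0]) / fc.p_f
        assert rel < 0.5   # independent runs, same law

    def test_standing_variants_less_deleterious_than_new_mutations(self):
        """Selection filters which mutations reach the target frequency, so
        the frequency-conditioned bins put more mass on weak effects than
        the new-mutation DFE does."""
        dem = DemographicModel.constant(150)
        sc = SampleConfig(S=300, f=0.02, n=2)
        n_anc = 150

        def sampler(rng, k):
            # gamma DFE over |4Ns| with a substantial deleterious tail
            g = rng.gamma(0.3, 120.0, size=k)
            return -g / (4 * n_anc)
        fc = dfe.estimate_frequency_conditionals(
            sampler, dem, sc, b=2, theta=60.0, n_sims=20, seed=3,
            horizon_factor=6)
        p_new = fc.n_sj / fc.n_total
        assert fc.p_s_given_f[0] > p_new[0]


class TestBootstrap:
    def make_data(self, n_loci, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for l in range(n_loci):
            p = rng.dirichlet([5, 3, 2])
            counts = rng.multinomial(30, p)
            for w, c in enumerate(counts, start=1):
                rows += [(l, "down", i, 1.0, w) for i in range(c)]
        recs = pd.DataFrame(rows, columns=["locus_id", "direction", "pair",
                                           "length_bp", "window"])
        return IBSData(recs, WindowScheme.equidistant(3, 10_000.0))

    def test_intervals_widen_with_fewer_loci(self):
        est = lambda counts: counts[0] / counts.sum()
        small = dfe.bootstrap(self.make_data(8, 1), est, B=120, seed=4)
        big = dfe.bootstrap(self.make_data(60, 2), est, B=120, seed=5)
        w_small = np.diff(small.intervals["estimate"])[0]
        w_big = np.diff(big.intervals["estimate"])[0]
        assert w_small > w_big

    def test_failed_replicates_counted_and_capped(self):
        data = self.make_data(10, 3)
        calls = {"i": 0}
        def flaky(counts):
            calls["i"] += 1
            if calls["i"] % 2:
                raise RuntimeError("boom")
            return 1.0
        with pytest.raises(RuntimeError):
            dfe.bootstrap(data, flaky, B=50, seed=6)

    def test_needs_two_loci(self):
        with pytest.raises(ValueError):
            dfe.bootstrap(self.make_data(1), lambda c: 0.0, B=10)
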