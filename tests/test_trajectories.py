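import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from haplodfe.demography import DemographicModel, SampleConfig, SelectionParams
from haplodfe import trajectories as tj


def direct_wf_sfs(n_dip, theta, generations, seed):
    """Independent oracle: per-generation loop over a dict of mutation counts."""
    rng = np.random.default_rng(seed)
    two_n = 2 * n_dip
    counts: list[int] = []
    for _ in range(generations):
        counts = [c for c in (int(rng.binomial(two_n, c / two_n)) for c in counts)
                  if 0 < c < two_n]
        counts.extend([1] * rng.poisson(theta / 2))
    return np.bincount(counts, minlength=two_n)


class TestSimulatePrf:
    def test_neutral_sfs_matches_one_over_i_and_oracle(self):
        """Neutral equilibrium: E[#variants at i copies] ~ theta/i."""
        dem = DemographicModel.constant(200)
        trajs = tj.simulate_prf(dem, SelectionParams(0.0), theta=40,
                                generations=12_000, seed=1)
        counts = np.bincount([t.final_count for t in trajs], minlength=400)
        oracle = direct_wf_sfs(200, 40, 12_000, seed=2)
        # coarse count-classes, compared against theory and the oracle
        bins = [(1, 2), (2, 4), (4, 8), (8, 16), (16, 64)]
        obs = np.array([counts[a:b].sum() for a, b in bins], dtype=float)
        exp = np.array([sum(40.0 / i for i in range(a, b)) for a, b in bins])
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 1e-3
        orc = np.array([oracle[a:b].sum() for a, b in bins], dtype=float)
        stat, p = chisquare(obs, orc * obs.sum() / orc.sum())
        assert p > 1e-3

    def test_expected_new_mutations_is_half_theta(self):
        dem = DemographicModel.constant(500)
        trajs = tj.simulate_prf(dem, SelectionParams(0.0), theta=1000,
                                generations=60, seed=3)
        # ages identify the injection generation; the most recent generation
        # received Poisson(500) new singletons
        newest = sum(1 for t in trajs if t.age == 1 and t.final_count == 1)
        assert newest == pytest.approx(500, abs=5 * np.sqrt(500))

    def test_neutral_update_is_martingale(self):
        x = np.linspace(0.01, 0.99, 13)
        assert np.allclose(tj.expected_frequency(x, 0.0), x)

    def test_invalid_theta_rejected(self):
        dem = DemographicModel.constant(100)
        with pytest.raises(ValueError):
            tj.simulate_prf(dem, SelectionParams(0.0), theta=0.0)


class TestConditioning:
    def test_zero_frequency_never_accepted(self):
        sc = SampleConfig(S=4000, f=0.01, n=2)
        assert not sc.accepts(0)

    def test_exact_band_means_exact_count(self, small_model):
        sc = SampleConfig(S=4000, f=0.01, n=2)
        dem = DemographicModel.constant(300)
        trajs = tj.simulate_prf(dem, SelectionParams(0.0), theta=60,
                                generations=3200, seed=4)
        kept = tj.condition_on_frequency(trajs, sc, seed=5)
        assert all(t.final_sample_count == 40 for t in kept)

    def test_no_accepted_trajectories_signal(self):
        dem = DemographicModel.constant(300)
        trajs = tj.simulate_prf(dem, SelectionParams(0.0), theta=60,
                                generations=3200, seed=6)
        sc = SampleConfig(S=4000, f=0.5, tolerance=0.0, n=2)  # unreachable band
        with pytest.raises(tj.NoAcceptedTrajectories):
            tj.condition_on_frequency(trajs, sc, seed=7)


class TestAlleleAge:
    def test_age_of_fresh_mutation_is_one(self):
        t = tj.Trajectory(np.array([1]), np.array([100]))
        assert tj.allele_age(t) == 1

    def test_neutral_mean_age_matches_closed_form(self, neutral_trajectories):
        """Kimura-Ohta: mean age of a neutral allele at frequency x is
        -4N (x/(1-x)) ln x; the binomial sample conditioning only smears
        this mildly."""
        ages = np.array([t.age for t in neutral_trajectories])
        x = 0.01
        closed = -4 * 300 * (x / (1 - x)) * np.log(x)
        se = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - closed) < max(4 * se, 0.25 * closed)

    def test_sign_symmetry_of_ages_under_constant_size(self):
        """Alleles under +|4Ns| and -|4Ns| at the same frequency have the
        same age distribution in a constant-size population.  The symmetry
        is a fixed-frequency property, so the sample conditioning uses a
        large S with a tolerance band, which pins the population frequency
        tightly (a loose binomial smear weights the two stationary
        frequency densities differently and breaks the comparison)."""
        dem = DemographicModel.constant(1000)
        sc = SampleConfig(S=20_000, f=0.01, tolerance=0.0005, n=1)
        plus = tj.sample_conditioned_trajectories(
            dem, SelectionParams(+100.0), 100.0, sc, 1000, seed=8)
        minus = tj.sample_conditioned_trajectories(
            dem, SelectionParams(-100.0), 100.0, sc, 1000, seed=9)
        ages_p = np.array([t.age for t in plus])
        ages_m = np.array([t.age for t in minus])
        stat = kstest(ages_p, ages_m)
        assert stat.pvalue > 0.01

    def test_stronger_selection_means_younger_alleles(self):
        dem = DemographicModel.constant(300)
        sc = SampleConfig(S=400, f=0.01, n=1)
        means = []
        for gamma in (0.0, -50.0, -100.0):
            trajs = tj.sample_conditioned_trajectories(
                dem, SelectionParams(gamma), 60.0, sc, 400, seed=int(10 - gamma))
            means.append(np.mean([t.age for t in trajs]))
        assert means[0] > means[1] > means[2]


class TestT2Distribution:
    def test_two_copy_trajectory_is_truncated_geometric(self):
        counts = np.array([1] + [2] * 10)
        t = tj.Trajectory(counts, np.full(11, 50))
        dist = tj.t2_distribution(t)
        # geometric with rate 1/2 over the nine two-copy parental steps,
        # then certain coalescence at the origin generation
        assert np.allclose(dist.pmf[:9], 0.5 ** np.arange(1, 10))
        assert dist.pmf[9] == pytest.approx(0.5 ** 9)
        assert dist.pmf[10] == pytest.approx(0.0)

    def test_pmf_sums_to_one(self, neutral_trajectories):
        for t in neutral_trajectories[:25]:
            assert tj.t2_distribution(t).pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_support_bounded_by_origin(self, one_trajectory):
        dist = tj.t2_distribution(one_trajectory)
        assert dist.times[-1] == one_trajectory.origin_time

    def test_matches_two_lineage_backward_simulation(self, one_trajectory):
        """Oracle: draw two lineages, walk backward, coalesce with
        probability 1/(parental count); compare empirical T2 pmf."""
        rng = np.random.default_rng(12)
        counts = one_trajectory.counts
        age = len(counts)
        draws = 60_000
        # two lineages pick parent labels uniformly within the derived class
        # each generation going backward; they coalesce on a label collision
        back = np.concatenate([counts[-2::-1], [1]])
        pa = rng.integers(0, back[None, :], size=(draws, age))
        pb = rng.integers(0, back[None, :], size=(draws, age))
        first = np.argmax(pa == pb, axis=1) + 1
        emp = np.bincount(first, minlength=age + 1)[1:] / draws
        ana = tj.t2_distribution(one_trajectory).pmf
        se = np.sqrt(np.maximum(ana * (1 - ana), 1e-12) / draws)
        big = ana > 0.002
        assert np.all(np.abs(emp[big] - ana[big]) < 3.5 * se[big] + 1e-9)


class TestSerialization:
    def test_round_trip(self, neutral_trajectories, tmp_path):
        path = tmp_path / "trajs.tsv"
        tj.write_trajectories(str(path), neutral_trajectories[:5],
                              {"demography": "constant-N300"})
        back = tj.read_trajectories(str(path))
        assert len(back) == 5
        for a, b in zip(neutral_trajectories[:5], back):
            assert np.array_equal(a.counts, b.counts)
            assert np.array_equal(a.pop_sizes, b.pop_sizes)
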