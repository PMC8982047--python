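import numpy as np
import pytest

from haplodfe.demography import DemographicModel, LocusParams, SelectionParams
from haplodfe import coalescent as coal
from haplodfe import trajectories as tj
from haplodfe.ibs import bin_lengths, pairwise_lengths_matrix


class TestSimulateHaplotypes:
    def test_zero_mutation_rate_gives_no_sites(self, small_model, one_trajectory):
        loc = LocusParams(u=0.0, r=3e-7, length=50_000, focal_pos=0.0)
        hs = coal.simulate_haplotypes(one_trajectory, small_model["demography"],
                                      loc, 4, seed=1)
        assert hs.n_sites == 0
        lengths = pairwise_lengths_matrix(hs.positions, hs.matrix, 0.0, "down")
        assert np.all(np.isinf(lengths))

    def test_n_above_final_copies_rejected(self, small_model, one_trajectory):
        with pytest.raises(ValueError):
            coal.simulate_haplotypes(one_trajectory, small_model["demography"],
                                     small_model["locus"],
                                     one_trajectory.final_count + 1, seed=1)

    def test_all_haplotypes_positions_inside_region(self, small_model,
                                                    one_trajectory):
        hs = coal.simulate_haplotypes(one_trajectory, small_model["demography"],
                                      small_model["locus"], 4, seed=2)
        assert np.all((hs.positions >= 0) & (hs.positions <= 50_000))
        assert hs.matrix.shape == (hs.n_sites, 4)
        # every segregating site is polymorphic among the carriers
        sums = hs.matrix.sum(axis=1)
        assert np.all((sums >= 1) & (sums <= 3))

    def test_r0_pair_matches_analytic_t2_closed_form(self, small_model,
                                                     one_trajectory):
        """With no recombination, P(L > d) for two haplotypes equals
        E[exp(-2 u T2 d)] under the analytic T2 pmf."""
        dem = small_model["demography"]
        u = 1.5e-6
        loc = LocusParams(u=u, r=0.0, length=50_000, focal_pos=0.0)
        dist = tj.t2_distribution(one_trajectory)
        ds = np.array([2_000.0, 8_000.0, 25_000.0])
        theory = np.array([np.sum(dist.pmf * np.exp(-2 * u * dist.times * d))
                           for d in ds])
        reps = 3000
        rng = np.random.default_rng(3)
        hits = np.zeros(len(ds))
        for _ in range(reps):
            hs = coal.simulate_haplotypes(one_trajectory, dem, loc, 2,
                                          int(rng.integers(2**31)))
            L = pairwise_lengths_matrix(hs.positions, hs.matrix, 0.0, "down")[0]
            hits += L > ds
        emp = hits / reps
        se = np.sqrt(theory * (1 - theory) / reps)
        assert np.all(np.abs(emp - theory) < 3 * se + 1e-12)

    def test_near_fixed_trajectory_recovers_neutral_diversity(self):
        """A trajectory pinned near fixation makes the derived class the
        whole population, so pairwise diversity approaches the neutral
        coalescent expectation 2 u l E[T2] with E[T2] = 2N."""
        n_dip = 120
        age = 3000
        counts = np.concatenate([[1], np.full(age - 1, 2 * n_dip - 1)])
        trajectory = tj.Trajectory(counts, np.full(age, n_dip))
        dem = DemographicModel.constant(n_dip)
        u = 2e-6
        loc = LocusParams(u=u, r=0.0, length=20_000, focal_pos=0.0)
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(400):
            hs = coal.simulate_haplotypes(trajectory, dem, loc, 2,
                                          int(rng.integers(2**31)))
            diffs.append(hs.n_sites)
        expected = 2 * u * loc.length * 2 * n_dip   # theta = 4 N u l / ... per pair
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - expected) < 3 * se + 0.05 * expected


class TestWindowProbabilities:
    def test_pmf_sums_to_one_and_pools_all_pairs(self, small_model,
                                                 one_trajectory):
        pmf = coal.window_probabilities(
            one_trajectory, small_model["demography"], small_model["locus"],
            4, small_model["scheme"], reps=5, seed=5)
        assert pmf.shape == (6,)
        assert pmf.sum() == pytest.approx(1.0)

    def test_u0_puts_all_mass_in_last_window(self, small_model, one_trajectory):
        loc = LocusParams(u=0.0, r=3e-7, length=50_000, focal_pos=0.0)
        pmf = coal.window_probabilities(
            one_trajectory, small_model["demography"], loc, 4,
            small_model["scheme"], reps=3, seed=6)
        assert np.allclose(pmf, [0, 0, 0, 0, 0, 1])

    def test_deterministic_given_seed(self, small_model, one_trajectory):
        args = (one_trajectory, small_model["demography"],
                small_model["locus"], 4, small_model["scheme"])
        a = coal.window_probabilities(*args, reps=4, seed=7)
        b = coal.window_probabilities(*args, reps=4, seed=7)
        assert np.array_equal(a, b)

    def test_doubling_reps_stays_within_sampling_error(self, small_model,
                                                       one_trajectory):
        args = (one_trajectory, small_model["demography"],
                small_model["locus"], 4, small_model["scheme"])
        a = coal.window_probabilities(*args, reps=40, seed=8)
        b = coal.window_probabilities(*args, reps=80, seed=9)
        n_a = 40 * 6
        se = np.sqrt(np.maximum(a * (1 - a), 1e-4) / n_a)
        assert np.all(np.abs(a - b) < 4 * se)

    def test_midpoint_focal_uses_both_directions(self, small_model,
                                                 one_trajectory):
        loc = LocusParams(u=1.5e-6, r=3e-7, length=50_000, focal_pos=25_000.0)
        hs = coal.simulate_haplotypes(one_trajectory, small_model["demography"],
                                      loc, 4, seed=10)
        assert hs.directions() == ("up", "down")


class TestSelectionSignal:
    def test_mean_ibs_length_grows_with_selection_strength(self, small_model):
        """Stronger selection at fixed frequency means younger alleles,
        shorter pairwise coalescent times and hence longer IBS tracts."""
        dem = small_model["demography"]
        sc = small_model["sample"]
        loc = small_model["locus"]
        scheme = small_model["scheme"]
        mean_w6 = []
        for gamma in (0.0, -100.0):
            trajs = tj.sample_conditioned_trajectories(
                dem, SelectionParams(gamma), 60.0, sc, 220,
                seed=int(20 + abs(gamma)))
            rng = np.random.default_rng(21)
            counts = np.zeros(6)
            for tr in trajs:
                hs = coal.simulate_haplotypes(tr, dem, loc, sc.n,
                                              int(rng.integers(2**31)))
                L = pairwise_lengths_matrix(hs.positions, hs.matrix, 0.0, "down")
                counts += np.bincount(bin_lengths(L, scheme), minlength=7)[1:]
            mean_w6.append(counts[-1] / counts.sum())
        assert mean_w6[1] > mean_w6[0]
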