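"""Preset study conditions used by the bundled examples, tests and
reproduction scripts.

These are rescaled versions of two canonical scenarios for 1%-frequency
variants: a constant-size population, and a recent ten-fold expansion.  The
rescaling keeps the population-scaled quantities (4Ns, theta, rho) fixed
while shrinking the population size, so that forward and coalescent
simulations run at desk scale; the per-base mutation rate of the simulated
locus is chosen, as one would for real data, so that the six IBS windows
each capture an informative share of the pooled L distribution (each
bounded window holds a non-negligible fraction of lengths), and the window
extent fits inside the simulated flank.
"""

from __future__ import annotations

from dataclasses import dataclass

from .demography import DemographicModel, LocusParams, SampleConfig
from .ibs import WindowScheme

#: population mutation rate of the forward PRF simulator (most ancient epoch)
THETA_PRF = 100.0


@dataclass(frozen=True)
class Study:
    demography: DemographicModel
    sample: SampleConfig
    locus: LocusParams
    scheme: WindowScheme
    theta_prf: float = THETA_PRF


def constant_study() -> Study:
    """Constant N=1,000; 1% variants, n=20 derived haplotypes of S=2,000."""
    return Study(
        demography=DemographicModel.constant(1000, label="constant-N1000"),
        sample=SampleConfig(S=2000, f=0.01, n=20),
        locus=LocusParams(u=4.4e-7, r=1e-7, length=125_000, focal_pos=62_500.0),
        scheme=WindowScheme.equidistant(6, 50_000.0),
    )


def expansion_study() -> Study:
    """Ten-fold expansion (500 -> 5,000 diploids) ten generations ago."""
    return Study(
        demography=DemographicModel.from_epochs(
            [(500, 1), (5000, 10)], label="expansion-500-5000"),
        sample=SampleConfig(S=2000, f=0.01, n=20),
        locus=LocusParams(u=4.4e-7, r=1e-7, length=125_000, focal_pos=62_500.0),
        scheme=WindowScheme.equidistant(6, 50_000.0),
    )


def build_study_table(study: Study, grid, seed: int, K: int = 4000,
                      reps: int = 3, sim_slots: int = 700):
    """Likelihood table for a study's conditions (shared-subset estimator)."""
    from .likelihood import build_table
    return build_table(grid, study.sample, study.demography, study.locus,
                       study.scheme, K=K, reps=reps, seed=seed,
                       sim_slots=sim_slots)


def simulate_window_counts(study: Study, trajectories, seed: int) -> "np.ndarray":
    """Window-count vector of one replicate: one haplotype set per locus,
    both directions, pooled."""
    import numpy as np
    from .coalescent import simulate_haplotypes
    from .ibs import bin_lengths, pairwise_lengths_matrix
    rng = np.random.default_rng(seed)
    counts = np.zeros(study.scheme.m, dtype=np.int64)
    for tr in trajectories:
        hs = simulate_haplotypes(tr, study.demography, study.locus,
                                 study.sample.n, int(rng.integers(2**31)))
        for direction in hs.directions():
            lengths = pairwise_lengths_matrix(
                hs.positions, hs.matrix, hs.focal_pos, direction)
            counts += np.bincount(bin_lengths(lengths, study.scheme),
                                  minlength=study.scheme.m + 1)[1:]
    return counts


def selection_replicates(study: Study, gamma: float, A: int,
                         n_replicates: int, seed: int,
                         s_sampler=None) -> "list":
    """Window-count vectors for ``n_replicates`` independent data sets of A
    loci each, generated under one 4Ns (or a DFE via ``s_sampler``).

    All replicates' trajectories come from one forward run (one burn-in,
    well-separated harvest snapshots), then are partitioned.
    """
    import numpy as np
    from .demography import SelectionParams
    from .trajectories import sample_conditioned_trajectories
    trajs = sample_conditioned_trajectories(
        study.demography, SelectionParams(gamma), study.theta_prf,
        study.sample, A * n_replicates, seed=seed, s_sampler=s_sampler)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(trajs))
    out = []
    for r in range(n_replicates):
        chunk = [trajs[i] for i in order[r * A:(r + 1) * A]]
        out.append((chunk, simulate_window_counts(study, chunk,
                                                  int(rng.integers(2**31)))))
    return out


def mean_age_ratio(seed: int, n_per_class: int = 2000,
                   gamma_strong: float = -100.0) -> dict:
    """Ratio of mean allele ages, neutral over |4Ns|=100, for 1%-frequency
    variants of a constant-size population (N=1,000, binomial sample of 400
    chromosomes), from forward simulation."""
    import numpy as np
    from .demography import SelectionParams
    from .trajectories import sample_conditioned_trajectories
    st = age_ratio_study()
    out = {}
    for label, gamma, sd in (("neutral", 0.0, 0),
                             ("selected", gamma_strong, 1)):
        trajs = sample_conditioned_trajectories(
            st.demography, SelectionParams(gamma), st.theta_prf, st.sample,
            n_per_class, seed=seed * 2 + sd)
        out[label] = float(np.mean([t.age for t in trajs]))
    out["ratio"] = out["neutral"] / out["selected"]
    out["n_per_class"] = n_per_class
    return out


def age_ratio_study() -> Study:
    """Allele-age comparison setup: constant N=1,000, 1% of 400 chromosomes."""
    return Study(
        demography=DemographicModel.constant(1000, label="constant-N1000"),
        sample=SampleConfig(S=400, f=0.01, n=1),
        locus=LocusParams(u=4.4e-7, r=1e-7, length=125_000, focal_pos=62_500.0),
        scheme=WindowScheme.equidistant(6, 50_000.0),
    )
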