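"""From the fitness effects of standing 1% variants to those of new
mutations.

Selection filters which mutations reach a 1% frequency, so standing variants
are systematically less deleterious than new mutations.  This script samples
1%-frequency variants under a published human DFE (gamma over |4Ns| with
shape 0.184, scale 1599.3) and a ten-fold-expansion demography, estimates
the frequency probabilities by forward simulation, and applies the Bayes
conversion to recover the new-mutation DFE on coarse bins.
"""

import numpy as np

from haplodfe import SelectionParams, sample_conditioned_trajectories
from haplodfe.dfe import (convert_dfef_to_dfe, estimate_frequency_conditionals,
                          gamma_bin_masses)
from haplodfe.presets import expansion_study

SHAPE, SCALE = 0.184, 1599.313
study = expansion_study()
n_anc = study.demography.ancient_size
sampler = lambda rng, k: -rng.gamma(SHAPE, SCALE, size=k) / (4 * n_anc)

print("estimating P(f|D) and P(f|s_j,D) by forward simulation...")
fc = estimate_frequency_conditionals(
    sampler, study.demography, study.sample, b=3, theta=400.0,
    n_sims=4, seed=1, horizon_factor=6, min_hits=100)

trajs = sample_conditioned_trajectories(
    study.demography, SelectionParams(0.0), study.theta_prf, study.sample,
    400, seed=2, s_sampler=sampler)
g = np.array([-t.selection for t in trajs])
bins = np.minimum((g / 5).astype(int), 2)
standing = np.bincount(bins, minlength=3) / len(bins)
new = convert_dfef_to_dfe(standing, fc).probabilities
true = gamma_bin_masses(SHAPE, SCALE, 3)

print("\n                      [0,5)   [5,10)  [10,inf)   (|4Ns| bins)")
print(f"standing 1% variants  {standing[0]:.3f}   {standing[1]:.3f}   {standing[2]:.3f}")
print(f"converted new-mut DFE {new[0]:.3f}   {new[1]:.3f}   {new[2]:.3f}")
print(f"generating DFE        {true[0]:.3f}   {true[1]:.3f}   {true[2]:.3f}")
print("\nStanding variants over-represent the weak bin; the conversion")
print("restores the deleterious tail of the new-mutation distribution.")
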