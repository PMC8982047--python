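"""Rejection-ABC inference of the population size from neutral IBS windows.

The selection machinery assumes the demography is known; in practice it is
first inferred from putatively neutral variants at the same frequency.  This
script simulates observed window proportions under a truth of N = 300 and
recovers it from log-uniform prior draws.
"""

from haplodfe import DemographicModel, LocusParams, SampleConfig
from haplodfe.abc import ABCConfig, PriorRange, abc_reject, neutral_summaries
from haplodfe.ibs import WindowScheme

sc = SampleConfig(S=400, f=0.01, n=4)
loc = LocusParams(u=1.5e-6, r=3e-7, length=50_000, focal_pos=0.0)
scheme = WindowScheme.equidistant(6, 20_000.0)

truth = 300
observed = neutral_summaries(DemographicModel.constant(truth), sc, loc,
                             scheme, A=40, seed=1, theta_prf=60.0)
print("observed neutral window proportions:", observed.round(3))

cfg = ABCConfig(model="constant",
                priors={"N": PriorRange(100, 1200, log=True)},
                n_prior_draws=120, acceptance_quantile=0.1, A=15,
                theta_prf=60.0)
post = abc_reject(observed, cfg, sc, loc, scheme, seed=2)
lo, hi = post.interval("N")
print(f"truth N = {truth}; posterior median {post.point_estimates['N']:.0f}, "
      f"5-95% interval [{lo:.0f}, {hi:.0f}]")
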