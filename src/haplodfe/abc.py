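"""Rejection-ABC inference of the demographic model from the IBS window
proportions of putatively neutral variants at the target frequency.

The summary statistic of a parameter draw is the pooled window-proportion
vector of A neutral loci conditioned at frequency f; the observed summary is
compared by Euclidean distance and the closest quantile of prior draws is
accepted (plain rejection, no post-acceptance adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .demography import DemographicModel, LocusParams, SampleConfig, SelectionParams
from .ibs import WindowScheme, bin_lengths, pairwise_lengths_matrix
from .coalescent import simulate_haplotypes
from .trajectories import NoAcceptedTrajectories, sample_conditioned_trajectories


@dataclass(frozen=True)
class PriorRange:
    lo: float
    hi: float
    log: bool = False   # log-uniform (for sizes) vs uniform (for times)

    def draw(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        return float(rng.uniform(self.lo, self.hi))


@dataclass
class ABCConfig:
    """Model family, priors and rejection settings."""

    model: Literal["constant", "expansion", "custom"]
    priors: dict[str, PriorRange]
    n_prior_draws: int = 500
    acceptance_quantile: float = 0.05
    A: int = 50
    reps_per_locus: int = 1
    theta_prf: float = 100.0
    builder: Callable[[dict], DemographicModel] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.acceptance_quantile <= 0.5:
            raise ValueError("acceptance_quantile must lie in (0, 0.5]")
        for name, pr in self.priors.items():
            if not (np.isfinite(pr.lo) and np.isfinite(pr.hi) and pr.lo < pr.hi):
                raise ValueError(f"improper prior for {name}")

    def build(self, params: dict) -> DemographicModel:
        if self.model == "constant":
            return DemographicModel.constant(int(round(params["N"])))
        if self.model == "expansion":
            return DemographicModel.from_epochs(
                [(int(round(params["N_ancient"])), 1),
                 (int(round(params["N_recent"])), int(round(params["t_expand"])))],
                label="expansion")
        if self.builder is None:
            raise ValueError("custom model family needs a builder")
        return self.builder(params)


@dataclass
class ABCPosterior:
    accepted: pd.DataFrame        # accepted parameter draws
    distances: np.ndarray         # distances of the accepted draws
    all_distances: np.ndarray
    point_estimates: dict         # posterior median per parameter

    def interval(self, name: str, lo: float = 5.0, hi: float = 95.0) -> tuple[float, float]:
        v = self.accepted[name].to_numpy()
        return float(np.percentile(v, lo)), float(np.percentile(v, hi))


def neutral_summaries(
    demography: DemographicModel,
    sample: SampleConfig,
    locus: LocusParams,
    scheme: WindowScheme,
    A: int,
    seed: int | np.random.Generator = 0,
    reps_per_locus: int = 1,
    theta_prf: float = 100.0,
) -> np.ndarray:
    """Pooled IBS window proportions of A neutral loci conditioned at f.

    Neutral trajectories are obtained by forward simulation with rejection
    on the present-day sample frequency; each locus contributes
    ``reps_per_locus`` haplotype sets and all directions implied by the
    focal position.  Returns a length-M probability vector.
    """
    rng = np.random.default_rng(seed)
    trajs = sample_conditioned_trajectories(
        demography, SelectionParams(0.0), theta_prf, sample, A,
        seed=rng.integers(2**31))
    counts = np.zeros(scheme.m, dtype=np.int64)
    for tr in trajs:
        for _ in range(reps_per_locus):
            hs = simulate_haplotypes(tr, demography, locus, sample.n,
                                     int(rng.integers(2**31)))
            for direction in hs.directions():
                lengths = pairwise_lengths_matrix(
                    hs.positions, hs.matrix, hs.focal_pos, direction)
                counts += np.bincount(bin_lengths(lengths, scheme),
                                      minlength=scheme.m + 1)[1:]
    return counts / counts.sum()


def abc_reject(
    observed_summary: np.ndarray,
    config: ABCConfig,
    sample: SampleConfig,
    locus: LocusParams,
    scheme: WindowScheme,
    seed: int | np.random.Generator = 0,
) -> ABCPosterior:
    """Plain rejection ABC on Euclidean summary distance.

    Draws ``n_prior_draws`` parameter sets from the priors, simulates each
    draw's neutral summary, and accepts the closest
    ``ceil(quantile * draws)``.  Point estimates are posterior medians.
    """
    observed = np.asarray(observed_summary, dtype=float)
    if len(observed) != scheme.m:
        raise ValueError("observed summary length does not match the scheme")
    rng = np.random.default_rng(seed)
    names = sorted(config.priors)
    rows, dists = [], []
    for _ in range(config.n_prior_draws):
        params = {name: config.priors[name].draw(rng) for name in names}
        dem = config.build(params)
        try:
            summary = neutral_summaries(
                dem, sample, locus, scheme, config.A,
                seed=rng.integers(2**31), reps_per_locus=config.reps_per_locus,
                theta_prf=config.theta_prf)
        except NoAcceptedTrajectories:
            continue
        rows.append(params)
        dists.append(float(np.linalg.norm(summary - observed)))
    if not rows:
        raise RuntimeError("no prior draw produced a summary")
    dists = np.asarray(dists)
    if np.allclose(dists, dists[0]):
        raise ValueError("degenerate summaries: all distances identical")
    n_accept = int(np.ceil(config.acceptance_quantile * len(rows)))
    order = np.argsort(dists, kind="stable")[:n_accept]
    accepted = pd.DataFrame([rows[i] for i in order])
    point = {name: float(accepted[name].median()) for name in names}
    return ABCPosterior(accepted, dists[order], dists, point)
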