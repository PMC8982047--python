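"""Importance sampling of allele-frequency trajectories conditioned on the
present-day sample frequency.

Sampling trajectories that end at a given frequency by forward rejection is
wasteful, so trajectories are *proposed* backward in time: starting from a
present-day population count drawn from the posterior of the count given the
observed derived sample count (under a uniform count prior), the count is
walked backward with the time-reversed neutral Wright-Fisher kernel

    q(y | x) ~ pi(y) * Binom(2 N_here, y / (2 N_back)).pmf(x),   pi(y) = 1/y

(``pi`` is the stationary frequency measure of neutral mutation-drift flux,
so for a neutral target the weights are nearly flat), until the walk reaches
one copy and originates.  Each proposal carries its own log-density;
reweighting by the forward Wright-Fisher/PRF target density at any candidate
4Ns then gives self-normalized, unbiased expectations over the conditional
trajectory distribution, with the effective sample size
``ESS = (sum w)^2 / sum w^2`` reporting how much of the proposal budget
survives the reweighting.  For population sizes too large to tabulate the
reversed kernel the plain binomial backward kernel
``X_{t-1} ~ Binomial(2 N_{t-1}, X_t / (2 N_t))`` is used instead; the
weights correct either choice.

One proposal set can serve a whole grid of candidate 4Ns values because the
proposal itself is selection-free; the per-4Ns weights and ESS differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom as _binom

from .demography import DemographicModel, SampleConfig, SelectionParams
from .trajectories import Trajectory, expected_frequency


class ProposalExhausted(RuntimeError):
    """Backward proposal failed to produce enough valid trajectories."""


def _final_count_proposal(demography: DemographicModel, sample: SampleConfig,
                          rng: np.random.Generator, size: int):
    """Draw present-day population counts X_T given the target sample count.

    X_T is proposed proportionally to ``Binom(S, X/2N).pmf(k)`` over all
    segregating counts (a flat prior on the count), which covers the full
    support of the conditional target; ``k`` is drawn uniformly from the
    accepted band.  Returns (counts, ks, log q) per draw.
    """
    two_n = 2 * demography.recent_size
    lo, hi = sample.count_band
    ks = rng.integers(lo, hi + 1, size=size)
    # the final population count must cover the n haplotypes to be sampled
    states = np.arange(max(1, sample.n), two_n)
    log_k_prob = -np.log(hi - lo + 1)
    counts = np.empty(size, dtype=np.int64)
    logq = np.empty(size)
    for k in np.unique(ks):
        sel = ks == k
        lp = _binom.logpmf(k, sample.S, states / two_n)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        idx = rng.choice(len(states), size=int(sel.sum()), p=w)
        counts[sel] = states[idx]
        logq[sel] = np.log(w[idx]) + log_k_prob
    return counts, ks, logq


class _ReversedKernel:
    """Tabulated reversed-neutral kernel for one (N_here, N_back) size pair.

    Row x holds the distribution of the parental count y in 1..2*N_back-1;
    cumulative rows allow vectorised inverse-CDF sampling.
    """

    def __init__(self, n_here: int, n_back: int):
        two_h, two_b = 2 * n_here, 2 * n_back
        y = np.arange(1, two_b)
        x = np.arange(0, two_h + 1)
        # log Binom(2N_here, y/2N_back).pmf(x) on an (x, y) grid
        from scipy.special import gammaln
        logp = np.log(y / two_b)
        log1m = np.log1p(-y / two_b)
        lg = (gammaln(two_h + 1) - gammaln(x + 1)[:, None]
              - gammaln(two_h - x + 1)[:, None]
              + x[:, None] * logp[None, :] + (two_h - x)[:, None] * log1m[None, :])
        m = np.exp(lg) / y[None, :]
        m = m[1:two_h]                       # rows x = 1..2N_here-1
        m /= m.sum(axis=1, keepdims=True)
        self.cum = np.cumsum(m, axis=1)
        self.prob = m
        # origin stop probability from one copy
        self.p_stop = float(np.exp(two_b * np.log1p(-1.0 / two_h)))

    def sample(self, xs: np.ndarray, rng: np.random.Generator):
        """Draw parental counts for current counts ``xs``; returns (y, logq)."""
        u = rng.random(len(xs))
        ys = np.empty(len(xs), dtype=np.int64)
        rows = self.cum[xs - 1]
        for i in range(len(xs)):
            ys[i] = int(np.searchsorted(rows[i], u[i])) + 1
        logq = np.log(self.prob[xs - 1, ys - 1])
        return ys, logq


def propose_trajectories(
    sample: SampleConfig,
    demography: DemographicModel,
    proposal_selection: SelectionParams | None = None,
    K: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    max_age: int | None = None,
    retry_factor: int = 100,
    kernel_size_cap: int = 2500,
) -> tuple[list[Trajectory], np.ndarray]:
    """Propose ``K`` trajectories ending in the accepted frequency band.

    Returns ``(trajectories, log_q)`` where ``log_q[i]`` is the log-density
    of trajectory ``i`` under its own generating mechanism.  Proposals whose
    backward walk jumps to zero from two or more copies (impossible under
    the forward target), fixes, or exceeds ``max_age`` (default ``200 *
    N_ancient``) are rejected and regenerated, up to ``retry_factor * K``
    attempts in total.

    ``proposal_selection`` is accepted for interface compatibility; the
    backward kernel is neutral regardless (the reweighting step supplies
    selection), so it is ignored.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    n_anc = demography.ancient_size
    cap = max_age if max_age is not None else 200 * n_anc
    trajectories: list[Trajectory] = []
    logqs: list[float] = []
    kernels: dict[tuple[int, int], _ReversedKernel] = {}
    attempts = 0
    while len(trajectories) < K:
        need = K - len(trajectories)
        attempts += need
        if attempts > retry_factor * K:
            raise ProposalExhausted(
                f"{len(trajectories)} of {K} proposals after {attempts} attempts")
        counts0, ks, logq0 = _final_count_proposal(demography, sample, rng, need)
        # walk all proposals backward in lockstep (they share the clock)
        paths = [[int(c)] for c in counts0]
        logq = logq0.copy()
        active = np.arange(need)
        x = counts0.astype(np.int64)
        done: list[int] = []
        t = 0
        while len(active):
            n_here = demography.size_at(t)
            n_back = demography.size_at(t + 1)
            xs = x[active]
            if max(n_here, n_back) <= kernel_size_cap:
                key = (n_here, n_back)
                kern = kernels.get(key)
                if kern is None:
                    kern = kernels[key] = _ReversedKernel(n_here, n_back)
                at_one = xs == 1
                stop = at_one & (rng.random(len(xs)) < kern.p_stop)
                logq[active[stop]] += np.log(kern.p_stop)
                walk = ~stop
                y = np.empty(len(xs), dtype=np.int64)
                if walk.any():
                    yw, lq = kern.sample(xs[walk], rng)
                    y[walk] = yw
                    logq[active[walk]] += lq
                    logq[active[at_one & walk]] += np.log1p(-kern.p_stop)
                origin = stop
                dead = np.zeros(len(xs), dtype=bool)
            else:
                p = xs / (2.0 * n_here)
                y = rng.binomial(2 * n_back, p)
                logq[active] += _binom.logpmf(y, 2 * n_back, p)
                origin = (y == 0) & (xs == 1)
                dead = ((y == 0) & (xs > 1)) | (y >= 2 * n_back)
            done.extend(active[origin])
            keep = ~(origin | dead)
            for i, yi in zip(active[keep], y[keep]):
                paths[i].append(int(yi))
            x[active[keep]] = y[keep]
            active = active[keep]
            t += 1
            if t > cap:
                break  # drop whatever is still walking
        for i in sorted(done):
            counts = np.asarray(paths[i][::-1], dtype=np.int64)
            pops = np.asarray(demography.size_trace(len(counts)), dtype=np.int64)
            if len(trajectories) < K:
                trajectories.append(
                    Trajectory(counts, pops, final_sample_count=int(ks[i])))
                logqs.append(float(logq[i]))
    return trajectories, np.asarray(logqs)


def log_target_density(
    trajectory: Trajectory,
    selection: SelectionParams,
    demography: DemographicModel,
    sample: SampleConfig,
) -> float:
    """Log forward density of a trajectory under the Wright-Fisher/PRF target.

    The density is the product of the origination intensity (proportional to
    the population size when the mutation arose, since the per-genome
    mutation rate is fixed), the per-generation Wright-Fisher binomial
    transition probabilities with selection, and the binomial probability of
    the recorded derived sample count at the present; 4Ns-independent
    constants are dropped (they cancel in the self-normalized estimator).
    An impossible transition yields ``-inf``.
    """
    return float(log_target_density_many([trajectory], selection, demography, sample)[0])


def log_target_density_many(
    trajectories: list[Trajectory],
    selection: SelectionParams,
    demography: DemographicModel,
    sample: SampleConfig,
) -> np.ndarray:
    """Vectorised :func:`log_target_density` over a list of trajectories."""
    n_anc = demography.ancient_size
    s = selection.s(n_anc)
    h = selection.dominance
    # flatten all transitions across trajectories
    xs, ys, n_from, n_to, owner = [], [], [], [], []
    out = np.zeros(len(trajectories))
    for i, tr in enumerate(trajectories):
        counts = tr.counts
        pops = tr.pop_sizes
        if np.any(counts[:-1] == 0):
            out[i] = -np.inf
            continue
        if len(counts) > 1:
            xs.append(counts[:-1])
            ys.append(counts[1:])
            n_from.append(pops[:-1])
            n_to.append(pops[1:])
            owner.append(np.full(len(counts) - 1, i))
        # origination intensity ~ theta(t0)/2 ~ N at origin
        out[i] += np.log(pops[0] / n_anc)
        # final binomial sampling of the recorded derived sample count; the
        # population must hold at least the n haplotypes to be sampled
        if counts[-1] < sample.n:
            out[i] = -np.inf
            continue
        k = tr.final_sample_count
        if k is not None:
            x_fin = counts[-1] / (2.0 * pops[-1])
            out[i] += _binom.logpmf(k, sample.S, x_fin)
    if xs:
        x = np.concatenate(xs) / (2.0 * np.concatenate(n_from))
        p = expected_frequency(x, s, h)
        lp = _binom.logpmf(np.concatenate(ys), 2 * np.concatenate(n_to), p)
        np.add.at(out, np.concatenate(owner), np.where(np.isfinite(lp), lp, -np.inf))
        # a zero-probability transition must dominate
        bad = np.flatnonzero(~np.isfinite(lp))
        if len(bad):
            out[np.unique(np.concatenate(owner)[bad])] = -np.inf
    return out


def ess(weights: np.ndarray) -> float:
    """Effective sample size ``(sum w)^2 / sum w^2`` of importance weights."""
    w = np.asarray(weights, dtype=float)
    if not np.any(w > 0):
        raise ValueError("all importance weights are zero")
    return float(w.sum() ** 2 / np.sum(w * w))


@dataclass
class WeightedTrajectorySet:
    """Proposal trajectories with per-4Ns log-weights and effective sizes."""

    trajectories: list[Trajectory]
    log_q: np.ndarray
    grid: np.ndarray                    # candidate 4Ns values
    log_weights: np.ndarray             # (len(grid), K), max-normalized
    ess: np.ndarray                     # per grid point

    @property
    def K(self) -> int:
        return len(self.trajectories)

    def weights(self, i: int) -> np.ndarray:
        """Normalized (sum-1) weights for grid point ``i``."""
        lw = self.log_weights[i]
        w = np.exp(lw - lw.max())
        return w / w.sum()

    def write(self, prefix: str) -> None:
        """Persist as text: trajectories TSV plus a per-4Ns log-weight TSV
        carrying the proposal log-density and ESS values."""
        from .trajectories import write_trajectories
        write_trajectories(f"{prefix}.trajectories.tsv", self.trajectories)
        with open(f"{prefix}.weights.tsv", "w") as fh:
            fh.write("# ess=" + ",".join(
                f"{g:g}:{e:.6g}" for g, e in zip(self.grid, self.ess)) + "\n")
            cols = "\t".join(f"logw_{g:g}" for g in self.grid)
            fh.write(f"trajectory_id\tproposal_logq\t{cols}\n")
            for k in range(self.K):
                vals = "\t".join(f"{self.log_weights[i, k]:.8g}"
                                 for i in range(len(self.grid)))
                fh.write(f"{k}\t{self.log_q[k]:.8g}\t{vals}\n")


def weight_trajectories(
    trajectories: list[Trajectory],
    log_q: np.ndarray,
    grid,
    demography: DemographicModel,
    sample: SampleConfig,
    dominance: float = 0.5,
) -> WeightedTrajectorySet:
    """Compute per-4Ns importance weights for a shared proposal set."""
    grid = np.asarray(grid, dtype=float)
    K = len(trajectories)
    log_w = np.empty((len(grid), K))
    ess_vals = np.empty(len(grid))
    for i, gamma in enumerate(grid):
        lt = log_target_density_many(
            trajectories, SelectionParams(gamma, dominance), demography, sample)
        lw = lt - log_q
        finite = np.isfinite(lw)
        if not finite.any():
            log_w[i] = -np.inf
            ess_vals[i] = 0.0
            continue
        lw = lw - lw[finite].max()
        log_w[i] = lw
        ess_vals[i] = ess(np.exp(np.where(finite, lw, -np.inf)))
    return WeightedTrajectorySet(trajectories, log_q, grid, log_w, ess_vals)
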