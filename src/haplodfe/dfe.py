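"""Distribution of fitness effects: for standing variants at a frequency
(the frequency-conditioned DFE) and for new mutations.

The frequency-conditioned DFE of variants observed at sample frequency f is
parameterised as a gamma distribution over deleterious 4Ns, discretized to
unit-width bins centred on the integers and tail-collapsed at a threshold
``tau``.  Its parameters (shape alpha, scale beta) are estimated by grid
search on a composite likelihood in which each IBS record's window
probability is averaged over the integer-4Ns likelihood tables weighted by
the discretized gamma.  Bayes' rule then converts the frequency-conditioned
distribution into the DFE of new mutations on coarse 4Ns bins, using
frequency probabilities estimated from forward PRF simulation:

    P(s_j) = P(s_j | f, D) * P(f | D) / P(f | s_j, D)

(valid because the DFE of new mutations does not depend on the demography).
Uncertainty is assessed by bootstrap over loci.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

from .demography import DemographicModel, SampleConfig
from .ibs import IBSData
from .likelihood import LikelihoodTable, default_floor
from . import trajectories as _tj

__all__ = [
    "DFEfParams", "DFEBins", "FrequencyConditionals", "discretized_gamma",
    "estimate_dfef", "estimate_frequency_conditionals", "convert_dfef_to_dfe",
    "bootstrap", "dfe_bin_edges", "gamma_bin_masses",
]


def discretized_gamma(alpha: float, beta: float, tau: int) -> np.ndarray:
    """Unit-bin discretized, tail-collapsed gamma pmf over 4Ns = 0..tau.

    ``pmf[g] = F(g+0.5) - F(max(g-0.5, 0))`` for g < tau and the last entry
    absorbs the upper tail, so the pmf sums to one exactly.
    """
    if alpha <= 0 or beta <= 0 or tau <= 0:
        raise ValueError("alpha, beta and tau must be positive")
    g = np.arange(0, int(tau) + 1)
    hi = _gamma.cdf(g + 0.5, a=alpha, scale=beta)
    lo = _gamma.cdf(np.maximum(g - 0.5, 0.0), a=alpha, scale=beta)
    if not (np.all(np.isfinite(hi)) and np.all(np.isfinite(lo))):
        raise FloatingPointError("non-finite gamma CDF evaluation")
    pmf = hi - lo
    pmf[-1] = 1.0 - lo[-1]
    return pmf


@dataclass
class DFEfParams:
    """Discretized-gamma parameters of the frequency-conditioned DFE."""

    alpha: float
    beta: float
    tau: int

    @property
    def pmf(self) -> np.ndarray:
        return discretized_gamma(self.alpha, self.beta, self.tau)

    @property
    def mean(self) -> float:
        """Mean 4Ns of the discretized, tail-collapsed distribution."""
        return float(np.arange(self.tau + 1) @ self.pmf)


# default search grids: a geometric ladder for the small-valued shape and a
# wide arithmetic ladder for the scale
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.03, 0.91, 0.03), 2))
DEFAULT_BETA_GRID = tuple(list(range(3, 211, 3)) + list(range(240, 2311, 30)))


def estimate_dfef(
    data: IBSData | np.ndarray,
    table: LikelihoodTable,
    tau: int,
    alpha_grid=DEFAULT_ALPHA_GRID,
    beta_grid=DEFAULT_BETA_GRID,
    ess_threshold: float = 100.0,
    floor: float | None = None,
) -> tuple[DFEfParams, np.ndarray]:
    """Composite-likelihood grid search for (alpha, beta) of the DFEf.

    ``table`` must cover every integer 4Ns in [0, tau] (a deleterious
    half-grid at unit spacing; 4Ns values are magnitudes here) with ESS at
    or above ``ess_threshold``.  Returns the MLE and the log-likelihood
    surface over ``alpha_grid x beta_grid``.
    """
    grid = table.grid
    need = np.arange(0, tau + 1, dtype=float)
    idx = np.searchsorted(grid, need)
    if (np.any(idx >= len(grid)) or not np.allclose(grid[idx], need)
            or np.any(table.ess[idx] < ess_threshold)
            or not table.available()[idx].all()):
        raise ValueError(
            f"table must cover integer 4Ns 0..{tau} with ESS >= {ess_threshold}")
    pmat = table.pmfs[idx]                     # (tau+1, M)
    eps = floor if floor is not None else default_floor(table)
    pmat = np.where(pmat <= 0, eps, pmat)
    pmat /= pmat.sum(axis=1, keepdims=True)
    counts = (data.window_counts() if isinstance(data, IBSData)
              else np.asarray(data, dtype=float))
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    surface = np.empty((len(alpha_grid), len(beta_grid)))
    for i, a in enumerate(alpha_grid):
        for j, b in enumerate(beta_grid):
            mix = discretized_gamma(a, b, tau) @ pmat    # (M,)
            surface[i, j] = counts @ np.log(mix)
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    return DFEfParams(float(alpha_grid[i]), float(beta_grid[j]), tau), surface


def dfe_bin_edges(b: int) -> list[tuple[float, float]]:
    """The b coarse DFE bins [5(i-1), 5i) with an open-ended last bin."""
    edges = [(5.0 * i, 5.0 * (i + 1)) for i in range(b - 1)]
    edges.append((5.0 * (b - 1), math.inf))
    return edges


def gamma_bin_masses(alpha: float, beta: float, b: int) -> np.ndarray:
    """Masses of a gamma(alpha, beta) distribution on the coarse DFE bins."""
    out = np.empty(b)
    for j, (lo, hi) in enumerate(dfe_bin_edges(b)):
        hi_c = 1.0 if math.isinf(hi) else _gamma.cdf(hi, a=alpha, scale=beta)
        out[j] = hi_c - _gamma.cdf(lo, a=alpha, scale=beta)
    return out


@dataclass
class DFEBins:
    """DFE over coarse 4Ns bins {[0,5), [5,10), ..., [5(b-1), inf)}."""

    probabilities: np.ndarray
    provenance: str = "estimated"
    renormalization_shift: float = 0.0   # total-variation mass moved
    flagged: np.ndarray | None = None    # bins shifted by >1% of total

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)

    @property
    def b(self) -> int:
        return len(self.probabilities)

    @property
    def edges(self) -> list[tuple[float, float]]:
        return dfe_bin_edges(self.b)


@dataclass
class FrequencyConditionals:
    """Monte-Carlo frequency probabilities connecting DFEf and DFE.

    All four count vectors come from the same forward simulations, so the
    Bayes identity is exact on them: ``n_sj_f/n_f * (n_f/n_total) /
    (n_sj_f/n_sj) = n_sj/n_total``.
    """

    p_f: float                     # P(f | D) under the generating DFE
    p_f_given_s: np.ndarray        # P(f | s_j, D) per bin
    p_s_given_f: np.ndarray        # P(s_j | f, D) per bin
    n_total: int
    n_f: int
    n_sj: np.ndarray
    n_sj_f: np.ndarray
    trunc_totals: np.ndarray | None = None   # mutations per truncated stratum
    trunc_hits: np.ndarray | None = None     # at-f events per truncated stratum

    def resampled(self, rng: np.random.Generator) -> "FrequencyConditionals":
        """Parametric resample of the Monte-Carlo counts behind the
        frequency probabilities (Poisson on the rare-event tallies), for
        propagating simulation uncertainty through the Bayes conversion."""
        n_f = max(int(rng.poisson(max(self.n_f, 1))), 1)
        if self.trunc_hits is not None:
            hits = np.maximum(rng.poisson(np.maximum(self.trunc_hits, 1)), 1)
            p_fs = hits / self.trunc_totals
        else:
            p_fs = self.p_f_given_s
        return FrequencyConditionals(
            n_f / self.n_total, p_fs, self.p_s_given_f,
            self.n_total, n_f, self.n_sj, self.n_sj_f,
            self.trunc_totals, self.trunc_hits)


class EmptyStratum(RuntimeError):
    pass


def _count_at_f(demography, sample, theta, horizon, s_sampler, rng):
    """One forward PRF run without trajectory recording; returns per-mutation
    (s, reached-f-at-present) tallies for every mutation that arose."""
    n_anc = demography.ancient_size
    recent = demography.recent_duration
    gens = horizon + recent
    sizes = demography.size_trace(gens)
    chrom = 2 * sizes[0]
    counts = np.empty(0, dtype=np.int64)
    sel = np.empty(0, dtype=float)
    ids = np.empty(0, dtype=np.int64)
    s_chunks: list[np.ndarray] = []
    next_id = 0
    for g in range(gens):
        lam = 0.5 * theta * sizes[g] / n_anc
        n_new = rng.poisson(lam)
        if n_new:
            new_s = np.asarray(s_sampler(rng, n_new), dtype=float)
            counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
            sel = np.concatenate([sel, new_s])
            ids = np.concatenate([ids, np.arange(next_id, next_id + n_new)])
            s_chunks.append(new_s)
            next_id += n_new
        if g + 1 < gens:
            p = _tj.expected_frequency(counts / float(chrom), sel)
            chrom = 2 * sizes[g + 1]
            nxt = rng.binomial(chrom, p)
            alive = (nxt > 0) & (nxt < chrom)
            counts, sel, ids = nxt[alive], sel[alive], ids[alive]
    ks = rng.binomial(sample.S, counts / float(chrom))
    lo, hi = sample.count_band
    ok = (ks >= lo) & (ks <= hi) & (counts >= sample.n)
    s_arr = (np.concatenate(s_chunks) if s_chunks else np.empty(0))
    f_arr = np.zeros(next_id, dtype=bool)
    f_arr[ids[ok]] = True
    return s_arr, f_arr


def estimate_frequency_conditionals(
    dfe_sampler,
    demography: DemographicModel,
    sample: SampleConfig,
    b: int,
    theta: float,
    n_sims: int = 20,
    seed: int | np.random.Generator = 0,
    *,
    horizon_factor: int = 8,
    gamma_of_s=None,
    min_hits: int = 25,
) -> FrequencyConditionals:
    """Estimate P(f|D), P(f|s_j,D) and P(s_j|f,D) by forward simulation.

    ``dfe_sampler(rng, k)`` draws k per-generation selection coefficients
    from the DFE of new mutations (as raw per-generation s; deleterious
    negative).  ``gamma_of_s`` maps s to the magnitude |4Ns| used for
    binning (default ``-4 N_ancient s``).  Each of ``n_sims`` runs evolves
    ``horizon_factor * N_ancient`` generations plus the recent epochs from
    an empty population; every mutation arising during a run is tallied,
    and "at f" means its present-day binomial sample count falls in the
    accepted band (with at least ``sample.n`` population copies).  The same
    tallies feed all three probabilities, so the horizon convention cancels
    in the Bayes conversion.  P(f|s_j,D) is estimated from additional runs
    with the DFE truncated to each bin.  Runs are extended beyond
    ``n_sims`` (up to 40x) until every estimated probability rests on at
    least ``min_hits`` at-frequency events.
    """
    rng = np.random.default_rng(seed)
    n_anc = demography.ancient_size
    if gamma_of_s is None:
        gamma_of_s = lambda s: -4.0 * n_anc * s
    edges = dfe_bin_edges(b)

    def bin_of(gammas):
        return np.minimum((np.asarray(gammas) / 5.0).astype(int), b - 1)

    horizon = horizon_factor * n_anc
    max_runs = 40 * n_sims
    s_all, f_all = [], []
    runs = 0
    # untruncated runs until the at-f count is statistically usable
    while runs < n_sims or (sum(int(f.sum()) for f in f_all) < min_hits
                            and runs < max_runs):
        s_arr, f_arr = _count_at_f(
            demography, sample, theta, horizon, dfe_sampler,
            np.random.default_rng(rng.integers(2**31)))
        s_all.append(s_arr)
        f_all.append(f_arr)
        runs += 1
    s_all = np.concatenate(s_all)
    f_all = np.concatenate(f_all)
    bins = bin_of(gamma_of_s(s_all))
    n_total = len(s_all)
    n_f = int(f_all.sum())
    n_sj = np.bincount(bins, minlength=b)
    n_sj_f = np.bincount(bins[f_all], minlength=b)
    if n_f == 0:
        raise EmptyStratum("no simulated mutation reached the target frequency")
    p_f = n_f / n_total
    p_s_given_f = n_sj_f / n_f

    # per-bin truncated runs for P(f | s_j, D)
    p_f_given_s = np.empty(b)
    trunc_totals = np.empty(b)
    trunc_hits = np.empty(b)
    for j, (lo, hi) in enumerate(edges):
        def trunc_sampler(r, k, lo=lo, hi=hi):
            out = np.empty(k)
            filled = 0
            while filled < k:
                cand = dfe_sampler(r, max(2 * (k - filled), 32))
                g = gamma_of_s(cand)
                keep = cand[(g >= lo) & (g < hi)]
                take = min(len(keep), k - filled)
                out[filled:filled + take] = keep[:take]
                filled += take
            return out
        tot_j = 0
        hit_j = 0
        runs = 0
        while runs < n_sims or (hit_j < min_hits and runs < max_runs):
            s_arr, f_arr = _count_at_f(
                demography, sample, theta, horizon, trunc_sampler,
                np.random.default_rng(rng.integers(2**31)))
            tot_j += len(s_arr)
            hit_j += int(f_arr.sum())
            runs += 1
        if hit_j == 0:
            raise EmptyStratum(
                f"no mutation in bin [{lo:g},{hi:g}) reached frequency f; "
                "increase n_sims")
        p_f_given_s[j] = hit_j / tot_j
        trunc_totals[j] = tot_j
        trunc_hits[j] = hit_j
    return FrequencyConditionals(p_f, p_f_given_s, p_s_given_f,
                                 n_total, n_f, n_sj, n_sj_f,
                                 trunc_totals, trunc_hits)


def convert_dfef_to_dfe(
    dfef_bins: np.ndarray,
    conditionals: FrequencyConditionals,
    flag_fraction: float = 0.01,
) -> DFEBins:
    """Bayes conversion from the frequency-conditioned bins to the DFE bins.

    Applies ``P(s_j) = P(s_j|f,D) P(f|D) / P(f|s_j,D)`` per bin and
    renormalizes to sum to one (Monte-Carlo noise breaks exact
    normalization); bins whose probability moved by more than
    ``flag_fraction`` of the total are flagged.
    """
    dfef_bins = np.asarray(dfef_bins, dtype=float)
    num = dfef_bins * conditionals.p_f
    den = conditionals.p_f_given_s
    bad = (den <= 0) & (num > 0)
    if bad.any():
        raise ZeroDivisionError(
            f"zero P(f|s_j,D) with nonzero DFEf mass in bins {np.flatnonzero(bad)}")
    raw = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all converted bin masses are zero")
    prob = raw / total
    shift = float(np.abs(prob - raw).sum())
    flagged = np.abs(prob - raw) > flag_fraction
    return DFEBins(prob, "estimated", shift, flagged)


@dataclass
class BootstrapResult:
    estimates: list
    intervals: dict          # name -> (lo, hi) percentile interval
    dropped: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"estimates": [np.asarray(e).tolist() if hasattr(e, "__len__")
                                     else e for e in self.estimates],
                       "intervals": {k: list(v) for k, v in self.intervals.items()},
                       "dropped": self.dropped}, fh, indent=1)


def bootstrap(
    data: IBSData,
    estimator,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    percentiles: tuple[float, float] = (5.0, 95.0),
    max_drop_fraction: float = 0.1,
) -> BootstrapResult:
    """Locus-level bootstrap: loci are resampled with replacement, each
    carrying its full block of IBS records, and ``estimator(window_counts)``
    is re-run per replicate.  Returns percentile intervals (90% by default)
    over the replicate estimates; replicates where the estimator raises are
    dropped, and more than ``max_drop_fraction`` drops fail the run.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    per_locus = data.per_locus_window_counts()
    if len(per_locus) < 2:
        raise ValueError("bootstrap needs at least two loci")
    rng = np.random.default_rng(seed)
    mat = per_locus.to_numpy(dtype=float)
    estimates = []
    dropped = 0
    for _ in range(B):
        pick = rng.integers(0, len(mat), size=len(mat))
        counts = mat[pick].sum(axis=0)
        try:
            estimates.append(estimator(counts))
        except Exception:
            dropped += 1
    if dropped > max_drop_fraction * B:
        raise RuntimeError(f"{dropped} of {B} bootstrap replicates failed")
    arr = np.asarray(estimates, dtype=float)
    lo, hi = percentiles
    if arr.ndim == 1:
        intervals = {"estimate": (float(np.percentile(arr, lo)),
                                  float(np.percentile(arr, hi)))}
    else:
        intervals = {f"bin{j}": (float(np.percentile(arr[:, j], lo)),
                                 float(np.percentile(arr[:, j], hi)))
                     for j in range(arr.shape[1])}
    return BootstrapResult(estimates, intervals, dropped)
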