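"""Composite-likelihood estimation of the population-scaled selection
coefficient 4Ns from window-binned IBS lengths.

For each candidate 4Ns on a grid, the per-window probability
``P(L in w_j | 4Ns, f, D)`` is the trajectory-space average of the
per-trajectory window pmf, taken under the conditional trajectory
distribution at that 4Ns.  The average is evaluated by importance sampling:
one selection-free backward proposal set of K trajectories serves the whole
grid; each grid point reweights it (with its own effective sample size), and
the expensive per-trajectory window pmfs are computed for a resampled
subset (sampling-importance-resampling) so that the simulation budget is
decoupled from K.  The composite log-likelihood of the data is then the sum
of log table probabilities over all records, and 4Ns is estimated by grid
search restricted to grid points whose ESS clears a threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .demography import DemographicModel, LocusParams, SampleConfig
from .ibs import IBSData, WindowScheme
from .coalescent import window_probabilities
from .importance import propose_trajectories, weight_trajectories

__all__ = [
    "LikelihoodTable", "SelectionEstimate", "build_table",
    "composite_loglik", "estimate_4Ns",
]


@dataclass
class LikelihoodTable:
    """Per-4Ns window pmfs with importance-sampling diagnostics."""

    grid: np.ndarray            # 4Ns values, strictly increasing
    pmfs: np.ndarray            # (len(grid), M); rows sum to 1 (or NaN if unavailable)
    ess: np.ndarray             # per grid point
    scheme: WindowScheme
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.pmfs = np.asarray(self.pmfs, dtype=float)
        self.ess = np.asarray(self.ess, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def m(self) -> int:
        return self.pmfs.shape[1]

    def available(self) -> np.ndarray:
        return ~np.isnan(self.pmfs).any(axis=1)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            fh.write("# windows=" + ",".join(str(b) for b in self.scheme.boundaries) + "\n")
            cols = "\t".join(f"w{j+1}" for j in range(self.m))
            fh.write(f"gamma\tess\t{cols}\n")
            for g, e, row in zip(self.grid, self.ess, self.pmfs):
                vals = "\t".join(f"{v:.10g}" for v in row)
                fh.write(f"{g:g}\t{e:.6g}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "LikelihoodTable":
        meta, rows = {}, []
        scheme = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# windows="):
                    scheme = WindowScheme(tuple(
                        float(x) for x in line.split("=", 1)[1].split(",")))
                elif line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    meta[k.strip()] = v
                elif line.startswith("gamma"):
                    continue
                else:
                    rows.append([float(x) for x in line.split()])
        arr = np.asarray(rows)
        return cls(arr[:, 0], arr[:, 2:], arr[:, 1], scheme, meta)


def build_table(
    grid,
    sample: SampleConfig,
    demography: DemographicModel,
    locus: LocusParams,
    scheme: WindowScheme,
    K: int = 1000,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    *,
    sim_slots: int | None = None,
    dominance: float = 0.5,
) -> LikelihoodTable:
    """Build the per-4Ns window-pmf table by importance sampling.

    ``K`` proposal trajectories are drawn once and reweighted per grid
    point.  ``sim_slots`` (default ``min(K, 200)``) controls the
    sampling-importance-resampling budget: per grid point that many
    trajectory slots are drawn with replacement from the weights and the
    window pmfs of the distinct trajectories (cached across grid points,
    ``reps`` haplotype sets each) are averaged with their multiplicities.
    With ``sim_slots >= K`` and flat weights this reduces to the plain
    weighted average over all K trajectories.
    """
    grid = np.asarray(sorted(float(g) for g in np.atleast_1d(grid)))
    rng = np.random.default_rng(seed)
    n = sample.n
    slots = sim_slots if sim_slots is not None else min(K, 200)
    trajs, logq = propose_trajectories(sample, demography, K=K, seed=rng)
    ws = weight_trajectories(trajs, logq, grid, demography, sample, dominance)
    # one resampled subset, drawn from the mixture of the per-grid-point
    # resampling laws, is shared by every grid point: each point reweights
    # the same simulated pmfs, so Monte-Carlo noise is common across the
    # grid and cancels from likelihood differences
    probs = np.zeros((len(grid), K))
    usable = []
    for i in range(len(grid)):
        w = ws.log_weights[i]
        finite = np.isfinite(w)
        if not finite.any():
            continue
        p = np.exp(w - w[finite].max())
        p[~finite] = 0.0
        probs[i] = p / p.sum()
        usable.append(i)
    pmfs = np.full((len(grid), scheme.m), np.nan)
    if usable:
        mix = probs[usable].mean(axis=0)
        picked = rng.choice(K, size=slots, p=mix)
        idx, mult = np.unique(picked, return_counts=True)
        sim_seeds = rng.integers(0, 2**31 - 1, size=len(idx))
        sims = np.empty((len(idx), scheme.m))
        for row, j in enumerate(idx):
            sims[row] = window_probabilities(
                trajs[j], demography, locus, n, scheme, reps=reps,
                seed=int(sim_seeds[row]))
        for i in usable:
            w_sub = mult * probs[i][idx] / mix[idx]
            pmfs[i] = (w_sub @ sims) / w_sub.sum()
    meta = dict(f=sample.f, S=sample.S, n=n, tolerance=sample.tolerance,
                demography=demography.label, u=locus.u, r=locus.r,
                l=locus.length, K=K, reps=reps, sim_slots=slots)
    return LikelihoodTable(grid, pmfs, ws.ess, scheme, meta)


def as_magnitude_table(table: LikelihoodTable) -> LikelihoodTable:
    """Re-index a deleterious half-grid table (4Ns <= 0) by |4Ns|.

    The frequency-conditioned DFE machinery works on magnitudes of
    deleterious 4Ns; this flips a table built on 0, -1, ..., -tau into one
    on 0, 1, ..., tau.
    """
    if np.any(table.grid > 0):
        raise ValueError("expected a non-positive (deleterious) grid")
    order = np.argsort(-table.grid)
    return LikelihoodTable(-table.grid[order], table.pmfs[order],
                           table.ess[order], table.scheme, dict(table.meta))


def default_floor(table: LikelihoodTable) -> float:
    """Probability floor for empty windows: 1 / (10 K reps C(n,2))."""
    k = int(table.meta.get("K", 1000))
    reps = int(table.meta.get("reps", 100))
    n = int(table.meta.get("n", 2))
    return 1.0 / (10.0 * k * reps * math.comb(n, 2))


def composite_loglik(
    data: IBSData | np.ndarray,
    table: LikelihoodTable,
    floor: float | None = None,
    warn=None,
) -> np.ndarray:
    """Composite log-likelihood surface over the table's 4Ns grid.

    ``data`` may be an :class:`IBSData` or a precomputed window-count
    vector.  Windows with zero estimated probability are floored at
    ``floor`` (see :func:`default_floor`) with a warning; unavailable grid
    points get ``nan``.
    """
    counts = (data.window_counts() if isinstance(data, IBSData)
              else np.asarray(data, dtype=float))
    if len(counts) != table.m:
        raise ValueError("data windows incompatible with table scheme")
    eps = floor if floor is not None else default_floor(table)
    surface = np.full(len(table.grid), np.nan)
    for i, row in enumerate(table.pmfs):
        if np.isnan(row).any():
            continue
        p = row.copy()
        zero = (p <= 0) & (counts > 0)
        if zero.any():
            if warn:
                warn(f"gamma={table.grid[i]:g}: {int(zero.sum())} observed "
                     f"window(s) with zero estimated probability floored at {eps:g}")
            p[p <= 0] = eps
            p /= p.sum()
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        if np.any(np.isneginf(logp) & (counts > 0)):
            surface[i] = -np.inf
        else:
            surface[i] = float(counts @ np.where(counts > 0, logp, 0.0))
    return surface


@dataclass
class SelectionEstimate:
    """Grid-search MLE of 4Ns with its ESS-gated surface."""

    mle: float
    grid: np.ndarray
    surface: np.ndarray          # total composite log-likelihood (nan if masked)
    gated_out: np.ndarray        # grid points masked by the ESS threshold
    ess_threshold: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mle_4Ns": self.mle,
                "grid": self.grid.tolist(),
                "surface": [None if np.isnan(v) else v for v in self.surface],
                "gated_out": self.grid[self.gated_out].tolist(),
                "ess_threshold": self.ess_threshold,
            }, fh, indent=1)


def _argmax_tiebreak(grid: np.ndarray, surface: np.ndarray) -> float:
    """Highest surface value; ties broken toward the smallest magnitude of
    4Ns and then the negative sign (conservative toward neutrality)."""
    best = np.nanmax(surface)
    cand = grid[np.flatnonzero(surface >= best - 1e-9)]
    cand = sorted(cand, key=lambda g: (abs(g), g))
    return float(cand[0])


def estimate_4Ns(
    data: IBSData,
    tables: "LikelihoodTable | list[LikelihoodTable] | dict",
    ess_threshold: float = 100.0,
    locus_strata: dict | None = None,
    floor: float | None = None,
) -> SelectionEstimate:
    """ESS-gated grid-search estimate of 4Ns, optionally stratified by the
    local recombination rate.

    With a single table, all records use it.  With several, each locus must
    be assigned to exactly one stratum: ``locus_strata`` maps locus_id to an
    index into ``tables`` — or, if omitted and ``data.locus_info`` carries a
    per-locus ``r`` column, each locus is matched to the table whose ``r``
    metadata is nearest in log-space.  The total surface is the sum of
    per-stratum composite surfaces; grid points where *any* stratum's ESS is
    below ``ess_threshold`` are masked.
    """
    if isinstance(tables, LikelihoodTable):
        tables = [tables]
    if isinstance(tables, dict):
        keys = sorted(tables)
        tables = [tables[k] for k in keys]
    grid = tables[0].grid
    for t in tables[1:]:
        if not np.array_equal(t.grid, grid):
            raise ValueError("all stratum tables must share one 4Ns grid")
    if len(tables) == 1:
        strata_counts = [data.window_counts()]
    else:
        if locus_strata is None:
            locus_strata = _nearest_r_strata(data, tables)
        locus_ids = data.records["locus_id"].unique()
        missing = [l for l in locus_ids if l not in locus_strata]
        if missing:
            raise ValueError(f"no stratum table for loci: {missing[:10]}")
        strata_counts = []
        for si in range(len(tables)):
            ids = [l for l in locus_ids if locus_strata[l] == si]
            strata_counts.append(data.window_counts(ids))
    total = np.zeros(len(grid))
    gated = np.zeros(len(grid), dtype=bool)
    for tab, counts in zip(tables, strata_counts):
        if counts.sum() == 0:
            continue
        surf = composite_loglik(counts, tab, floor=floor)
        gated |= (tab.ess < ess_threshold) | np.isnan(surf)
        total = total + np.where(np.isnan(surf), 0.0, surf)
    total[gated] = np.nan
    if np.all(np.isnan(total)):
        raise ValueError("every grid point is masked by the ESS threshold")
    mle = _argmax_tiebreak(grid, total)
    return SelectionEstimate(mle, grid, total, gated, ess_threshold)


def _nearest_r_strata(data: IBSData, tables) -> dict:
    if data.locus_info is None or "r" not in data.locus_info.columns:
        raise ValueError("per-locus r values required to assign strata")
    table_r = np.array([float(t.meta["r"]) for t in tables])
    out = {}
    for locus_id, row in data.locus_info.iterrows():
        lr = float(row["r"])
        with np.errstate(divide="ignore"):
            d = np.abs(np.log(np.maximum(table_r, 1e-300)) - np.log(max(lr, 1e-300)))
        out[locus_id] = int(np.argmin(d))
    return out
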