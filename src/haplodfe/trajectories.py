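"""Forward-in-time Wright-Fisher simulation under the Poisson Random Field
model, conditioning of allele-frequency trajectories on present-day sample
frequency, allele ages, and the analytic pairwise coalescent time T2.

The forward simulator injects ``Poisson(theta/2)`` new unlinked mutations per
generation, each starting at one copy, and propagates every segregating
mutation with binomial Wright-Fisher sampling around the selection-adjusted
expected frequency for genotype fitnesses 1, 1+2hs, 1+2s (ancestral
homozygote, heterozygote, derived homozygote):

    x' = x (1 + 2 s h + 2 s (1 - h) x) / (1 + 4 s h x (1 - x) + 2 s x^2)

with dominance ``h`` (default 1/2, so the heterozygote effect is ``s`` — the
standard genic parameterisation of ``4Ns``).  Trajectories record the integer
copy count per generation from origin (count 1) to the present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .demography import DemographicModel, SampleConfig, SelectionParams


@dataclass
class Trajectory:
    """Derived-allele copy counts per generation, origin (count 1) to present."""

    counts: np.ndarray
    pop_sizes: np.ndarray  # diploid size per recorded generation
    final_sample_count: int | None = None
    selection: float | None = None  # gamma used to generate it, if known

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.pop_sizes = np.asarray(self.pop_sizes, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-d vector")
        if len(self.counts) != len(self.pop_sizes):
            raise ValueError("counts and pop_sizes must be the same length")
        if self.counts[0] != 1:
            raise ValueError("a trajectory must start at one copy")
        chrom = 2 * self.pop_sizes
        if np.any(self.counts <= 0) or np.any(self.counts >= chrom):
            raise ValueError("all counts must be segregating: 0 < count < 2N")

    @property
    def age(self) -> int:
        """Allele age in generations (number of recorded generations)."""
        return len(self.counts)

    @property
    def origin_time(self) -> int:
        """Generations before present at which the allele arose."""
        return len(self.counts)

    @property
    def final_count(self) -> int:
        return int(self.counts[-1])

    def frequencies(self) -> np.ndarray:
        return self.counts / (2.0 * self.pop_sizes)


def allele_age(trajectory: Trajectory) -> int:
    """Age of the allele in generations (1 = arose this generation)."""
    return trajectory.age


@dataclass(frozen=True)
class T2Distribution:
    """Pmf of the pairwise coalescent time of two derived-allele lineages."""

    times: np.ndarray  # generations before present, 1..age
    pmf: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.sum(self.times * self.pmf))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum((self.times - m) ** 2 * self.pmf)))


def t2_distribution(trajectory: Trajectory, demography: DemographicModel | None = None) -> T2Distribution:
    """Analytic pmf of T2 for two lineages carrying the derived allele.

    Going backward one generation at a time, two lineages in the derived
    class coalesce with probability ``1/c`` where ``c`` is the derived copy
    count in the parental generation; coalescence is certain at the origin
    generation, where the count is 1.  The ``demography`` argument is
    accepted for interface symmetry but the trajectory itself carries all
    the information needed.
    """
    counts = trajectory.counts
    age = len(counts)
    # parental counts seen going backward: counts[age-2], ..., counts[0]
    back = counts[-2::-1].astype(float) if age > 1 else np.array([], dtype=float)
    hazard = np.concatenate([1.0 / back, [1.0]]) if age > 1 else np.array([1.0])
    surv = np.concatenate([[1.0], np.cumprod(1.0 - hazard[:-1])])
    pmf = hazard * surv
    times = np.arange(1, age + 1)
    return T2Distribution(times=times, pmf=pmf)


# ---------------------------------------------------------------------------
# Forward PRF simulation


def expected_frequency(x, s, h=0.5):
    """Post-selection expected derived frequency for fitnesses 1, 1+2hs, 1+2s."""
    x = np.asarray(x, dtype=float)
    if np.ndim(s) == 0 and s == 0.0:
        return x
    num = x * (1.0 + 2.0 * s * h + 2.0 * s * (1.0 - h) * x)
    den = 1.0 + 4.0 * s * h * x * (1.0 - x) + 2.0 * s * x * x
    return np.minimum(np.maximum(num / den, 0.0), 1.0)


class _Cohort:
    """Vectorised cohort of segregating mutations with optional histories."""

    __slots__ = ("counts", "sel", "histories", "record", "rng", "h", "_chrom")

    def __init__(self, rng: np.random.Generator, record: bool, dominance: float):
        self.counts = np.empty(0, dtype=np.int64)
        self.sel = np.empty(0, dtype=float)  # per-mutation s
        self.histories: list[list[int]] = []
        self.record = record
        self.rng = rng
        self.h = dominance
        self._chrom = 0

    def inject(self, n_new: int, new_s: np.ndarray) -> None:
        """Add ``n_new`` fresh mutations at one copy each."""
        if not n_new:
            return
        self.counts = np.concatenate([self.counts, np.ones(n_new, dtype=np.int64)])
        self.sel = np.concatenate([self.sel, np.asarray(new_s, dtype=float)])
        if self.record:
            self.histories.extend([1] for _ in range(n_new))

    def step(self, n_next_chrom: int) -> None:
        """Drift every mutation one generation into ``n_next_chrom`` chromosomes."""
        if len(self.counts):
            x = self.counts / float(self._chrom)
            p = expected_frequency(x, self.sel, self.h)
            new_counts = self.rng.binomial(n_next_chrom, p)
            alive = (new_counts > 0) & (new_counts < n_next_chrom)
            self.counts = new_counts[alive]
            self.sel = self.sel[alive]
            if self.record:
                idx = np.flatnonzero(alive)
                hist = self.histories
                self.histories = [hist[i] for i in idx]
                for lst, c in zip(self.histories, self.counts):
                    lst.append(int(c))
        self._chrom = n_next_chrom


def simulate_prf(
    demography: DemographicModel,
    selection: SelectionParams,
    theta: float,
    generations: int | None = None,
    seed: int | np.random.Generator = 0,
    *,
    burn_in_factor: int = 10,
    s_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    record: bool = True,
) -> list[Trajectory]:
    """Forward Poisson-Random-Field simulation; returns trajectories of all
    mutations segregating at the final generation.

    ``theta`` is the population mutation rate of the most ancient epoch; the
    expected number of new mutations per generation while the population has
    size N is ``theta/2 * N/N_ancient`` (the influx tracks the size, i.e.
    the per-genome rate is held fixed).  ``generations`` defaults to
    ``burn_in_factor * N_ancient`` plus the recent (post-ancient-epoch)
    duration, long enough to reach mutation-selection balance.

    ``s_sampler(rng, k)`` may supply per-mutation selection coefficients
    (e.g. draws from a DFE); by default every mutation uses
    ``selection.s(N_ancient)``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    n_anc = demography.ancient_size
    recent = demography.recent_duration
    min_gens = burn_in_factor * n_anc + recent
    if generations is None:
        generations = min_gens
    elif generations < recent + 1:
        raise ValueError("generations must cover the post-ancient epochs")
    s_fixed = selection.s(n_anc)

    cohort = _Cohort(rng, record, selection.dominance)
    sizes = demography.size_trace(generations)
    cohort._chrom = 2 * sizes[0]
    for g in range(generations):
        # new mutations enter generation g at one copy ...
        lam = 0.5 * theta * sizes[g] / n_anc
        n_new = rng.poisson(lam)
        new_s = (s_sampler(rng, n_new) if s_sampler is not None
                 else np.full(n_new, s_fixed))
        cohort.inject(n_new, new_s)
        # ... then drift carries everything into generation g+1
        if g + 1 < generations:
            cohort.step(2 * sizes[g + 1])
    out: list[Trajectory] = []
    if record:
        for hist, s in zip(cohort.histories, cohort.sel):
            counts = np.asarray(hist, dtype=np.int64)
            age = len(counts)
            pops = np.asarray(demography.size_trace(age), dtype=np.int64)
            out.append(Trajectory(counts, pops, selection=float(4 * n_anc * s)))
    return out


class NoAcceptedTrajectories(RuntimeError):
    """Raised when frequency conditioning rejects every trajectory."""


def condition_on_frequency(
    trajectories: Iterable[Trajectory],
    sample: SampleConfig,
    seed: int | np.random.Generator = 0,
    *,
    require_n_copies: bool = True,
) -> list[Trajectory]:
    """Binomially sample each trajectory's final population frequency with S
    chromosomes and retain trajectories whose derived sample count falls in
    the accepted band ``f +- tolerance``.

    By default a retained trajectory must also hold at least ``sample.n``
    derived copies in the population, since ``n`` distinct carrier
    haplotypes are to be drawn from it (the binomial sample count can
    otherwise exceed the population count when S is comparable to 2N).
    """
    rng = np.random.default_rng(seed)
    min_copies = sample.n if require_n_copies else 1
    kept: list[Trajectory] = []
    total = 0
    for tr in trajectories:
        total += 1
        if tr.final_count < min_copies:
            continue
        x = tr.final_count / (2.0 * tr.pop_sizes[-1])
        k = int(rng.binomial(sample.S, x))
        if sample.accepts(k):
            tr2 = Trajectory(tr.counts, tr.pop_sizes, final_sample_count=k,
                             selection=tr.selection)
            kept.append(tr2)
    if total and not kept:
        raise NoAcceptedTrajectories(
            f"0 of {total} trajectories accepted at f={sample.f}"
            f" +- {sample.tolerance} (S={sample.S})")
    return kept


def sample_conditioned_trajectories(
    demography: DemographicModel,
    selection: SelectionParams,
    theta: float,
    sample: SampleConfig,
    n_target: int,
    seed: int | np.random.Generator = 0,
    *,
    burn_in_factor: int = 10,
    snapshot_interval: int | None = None,
    max_snapshots: int = 100_000,
    s_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    visit_thinning: float = 0.2,
) -> list[Trajectory]:
    """Draw trajectories from the frequency-conditioned stationary ensemble.

    For a constant-size model the mutations of the Poisson Random Field are
    independent, so the ensemble is sampled exactly and without burn-in from
    batches of single-mutation Wright-Fisher paths, accepting every
    (path, generation) visit with its binomial band probability.

    For a nonequilibrium model the ancient epoch is burned in once
    (``burn_in_factor * N_ancient`` generations), and the recent epochs are
    then replayed repeatedly from checkpoints of the ancient standing
    variation, the checkpoint advancing ``snapshot_interval`` generations
    (default ``max(N_ancient // 10, 50)``) between replays; each replay's
    present-day standing variation is sampled binomially and matching
    trajectories are copied out until ``n_target`` have been accepted.
    """
    rng = np.random.default_rng(seed)
    n_anc = demography.ancient_size
    recent = demography.recent_duration
    interval = snapshot_interval or max(n_anc // 10, 50)
    s_fixed = selection.s(n_anc)
    accepted: list[Trajectory] = []

    if recent == 0:
        # constant-size model: under the Poisson Random Field mutations are
        # independent, so the stationary conditional ensemble can be sampled
        # without burn-in: simulate single-mutation Wright-Fisher paths from
        # one copy and accept each (path, generation) visit with the
        # probability that its binomial sample draw lands in the band.  This
        # is exactly the visit-weighted renewal ensemble of the long-run
        # cohort simulation, with far less correlation between draws.
        return _constant_conditioned_paths(
            n_anc, selection, sample, n_target, rng,
            s_sampler=s_sampler, max_batches=max_snapshots,
            visit_thinning=visit_thinning)

    # nonequilibrium model: burn in once in the ancient state, then replay the
    # recent epochs repeatedly from checkpoints of the ancient standing
    # variation, refreshing the checkpoint between replays
    cohort = _Cohort(rng, True, selection.dominance)
    chrom_anc = 2 * n_anc
    cohort._chrom = chrom_anc

    def evolve_ancient(gens: int) -> None:
        lam = 0.5 * theta
        for _ in range(gens):
            n_new = rng.poisson(lam)
            new_s = (s_sampler(rng, n_new) if s_sampler is not None
                     else np.full(n_new, s_fixed))
            cohort.inject(n_new, new_s)
            cohort.step(chrom_anc)

    evolve_ancient(burn_in_factor * n_anc)
    recent_sizes = demography.size_trace(recent + 1)  # ancient boundary .. present
    replays = 0
    while len(accepted) < n_target:
        if replays >= max_snapshots:
            raise NoAcceptedTrajectories(
                f"only {len(accepted)} of {n_target} accepted after {replays} replays")
        work = _Cohort(rng, True, selection.dominance)
        work.counts = cohort.counts.copy()
        work.sel = cohort.sel.copy()
        work.histories = [list(h) for h in cohort.histories]
        work._chrom = chrom_anc
        for g in range(recent):
            lam = 0.5 * theta * recent_sizes[g] / n_anc
            n_new = rng.poisson(lam)
            new_s = (s_sampler(rng, n_new) if s_sampler is not None
                     else np.full(n_new, s_fixed))
            work.inject(n_new, new_s)
            work.step(2 * recent_sizes[g + 1])
        x = work.counts / float(work._chrom)
        ks = rng.binomial(sample.S, x)
        ok = [sample.accepts(int(k)) and c >= sample.n
              for k, c in zip(ks, work.counts)]
        for i in np.flatnonzero(ok):
            counts = np.asarray(work.histories[i], dtype=np.int64)
            pops = np.asarray(demography.size_trace(len(counts)), dtype=np.int64)
            accepted.append(Trajectory(
                counts, pops, final_sample_count=int(ks[i]),
                selection=float(4 * n_anc * work.sel[i])))
        replays += 1
        evolve_ancient(interval)
    return accepted[:n_target]


def _draw_band_count(rng: np.random.Generator, sample: SampleConfig,
                     count: int, chrom: int) -> int:
    """Sample the derived sample count from the band-truncated binomial."""
    from scipy.stats import binom as _binom
    lo, hi = sample.count_band
    if lo == hi:
        return lo
    ks = np.arange(lo, hi + 1)
    pmf = _binom.pmf(ks, sample.S, count / chrom)
    tot = pmf.sum()
    if tot <= 0:
        return lo
    return int(rng.choice(ks, p=pmf / tot))


def _constant_conditioned_paths(
    n_anc: int,
    selection: SelectionParams,
    sample: SampleConfig,
    n_target: int,
    rng: np.random.Generator,
    *,
    s_sampler=None,
    batch: int = 2048,
    max_batches: int = 5000,
    visit_thinning: float = 0.2,
) -> list[Trajectory]:
    """Visit-weighted path-ensemble sampler for a constant-size population.

    Batches of single-mutation Wright-Fisher paths start at one copy; at
    every generation each segregating path is accepted, independently, with
    the probability that a binomial sample of S chromosomes would land in
    the accepted frequency band (and the population holds >= n copies), in
    which case its history up to that generation becomes one conditioned
    trajectory.  All visit probabilities are scaled down by
    ``visit_thinning``, which leaves the sampled ensemble unchanged (the
    scale cancels) while making repeat acceptances of the same long-lived
    path rare, so that draws are close to independent.  Paths are stepped
    as one vectorised block while many are alive and individually once
    survivors are rare.
    """
    from scipy.stats import binom as _binom
    chrom = 2 * n_anc
    s_fixed = selection.s(n_anc)
    h = selection.dominance
    lo, hi = sample.count_band
    cnt = np.arange(chrom + 1)
    accept_p = (_binom.cdf(hi, sample.S, cnt / chrom)
                - _binom.cdf(lo - 1, sample.S, cnt / chrom))
    accept_p *= visit_thinning
    accept_p[:max(sample.n, 1)] = 0.0
    accept_p[0] = 0.0
    dense_until = 3 * n_anc
    cap = 120 * n_anc
    accepted: list[Trajectory] = []
    batches = 0
    while len(accepted) < n_target:
        batches += 1
        if batches > max_batches:
            raise NoAcceptedTrajectories(
                f"only {len(accepted)} of {n_target} trajectories accepted"
                f" after {batches} path batches")
        counts = np.ones(batch, dtype=np.int64)
        sel = (np.asarray(s_sampler(rng, batch), dtype=float)
               if s_sampler is not None else np.full(batch, s_fixed))
        hist: list[np.ndarray] = [counts.astype(np.int32)]
        t = 0
        # dense phase: whole batch stepped together
        while t < dense_until and counts.any():
            pa = accept_p[counts]
            for i in np.flatnonzero(rng.random(batch) < pa):
                path = np.array([col[i] for col in hist], dtype=np.int64)
                accepted.append(Trajectory(
                    path, np.full(len(path), n_anc, dtype=np.int64),
                    final_sample_count=_draw_band_count(
                        rng, sample, int(counts[i]), chrom),
                    selection=float(4 * n_anc * sel[i])))
            p = expected_frequency(counts / float(chrom), sel, h)
            counts = rng.binomial(chrom, p)
            counts[counts == chrom] = 0  # fixed: no longer segregating
            hist.append(counts.astype(np.int32))
            t += 1
        # sparse phase: few survivors, stepped individually to absorption
        for i in np.flatnonzero(counts):
            path = [int(col[i]) for col in hist]
            c = path[-1]
            s_i = float(sel[i])
            tt = t
            while 0 < c < chrom and tt < cap:
                if rng.random() < accept_p[c]:
                    accepted.append(Trajectory(
                        np.asarray(path, dtype=np.int64),
                        np.full(len(path), n_anc, dtype=np.int64),
                        final_sample_count=_draw_band_count(rng, sample, c, chrom),
                        selection=float(4 * n_anc * s_i)))
                c = int(rng.binomial(chrom, float(
                    expected_frequency(c / chrom, s_i, h))))
                if c == chrom:
                    c = 0
                    break
                if c:
                    path.append(c)
                tt += 1
    # acceptances accrue in age order within a batch, so subsample the
    # overshoot uniformly rather than truncating (which would keep only the
    # youngest visits)
    order = rng.permutation(len(accepted))[:n_target]
    return [accepted[i] for i in order]


# ---------------------------------------------------------------------------
# Serialization: tab-separated text, one row per generation


def write_trajectories(path: str, trajectories: Sequence[Trajectory],
                       metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("trajectory_id\tgen_before_present\tcopies\tpop_size\n")
        for tid, tr in enumerate(trajectories):
            age = tr.age
            for i, (c, n) in enumerate(zip(tr.counts, tr.pop_sizes)):
                fh.write(f"{tid}\t{age - 1 - i}\t{c}\t{n}\n")


def read_trajectories(path: str) -> list[Trajectory]:
    rows: dict[int, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("trajectory_id"):
                continue
            tid, gbp, c, n = line.split()
            rows.setdefault(int(tid), []).append((int(gbp), int(c), int(n)))
    out = []
    for tid in sorted(rows):
        recs = sorted(rows[tid], key=lambda r: -r[0])
        out.append(Trajectory(np.array([r[1] for r in recs]),
                              np.array([r[2] for r in recs])))
    return out
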