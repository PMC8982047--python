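"""Backward-in-time structured coalescent conditional on an allele-frequency
trajectory, with recombination and infinite-sites mutation.

``n`` sampled haplotypes all carry the derived allele at a focal site.  Going
backward one generation at a time while the allele segregates, every lineage
belongs to one of two backgrounds: the *derived* class, whose size is the
trajectory's copy count, and the *ancestral* class, of size ``2N(t) -
count``.  Lineages pick parents uniformly within their class, so pairs (or
multiple lineages) choosing the same parent coalesce — the exact discrete
Wright-Fisher genealogy given the class sizes, whose two-lineage law is the
``1/c_t`` pairwise coalescence probability of the analytic T2 formula.
Recombination detaches the part of a lineage's material on the far side of a
breakpoint from the focal site; the detached piece rejoins the derived
background with probability ``x(t)`` (the population derived frequency) and
the ancestral background otherwise.  At the origin generation the last
derived lineage's material transfers to the ancestral background (the
mutation arose on an ancestral chromosome) and the process continues as an
unconditional coalescent under the demography until every part of the region
has reached its local most recent common ancestor.

Mutations are dropped with rate ``u`` per base per generation on every
branch segment while it is ancestral to a strict subset of the sample, at
continuous (infinite-sites) positions.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .demography import DemographicModel, LocusParams
from .ibs import WindowScheme, bin_lengths, pairwise_lengths_matrix
from .trajectories import Trajectory

DERIVED, ANCESTRAL = 0, 1


@dataclass
class HaplotypeSet:
    """n haplotypes around a focal derived allele carried by all of them.

    ``positions`` are continuous bp coordinates of segregating sites in
    ``[0, length]`` (the focal site itself is not listed) and ``matrix`` is
    the (sites x n) 0/1 allele matrix.
    """

    positions: np.ndarray
    matrix: np.ndarray
    focal_pos: float
    length: int

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def directions(self) -> tuple[str, ...]:
        """IBS directions available given where the focal site sits."""
        out = []
        if self.focal_pos > 0:
            out.append("up")
        if self.focal_pos < self.length:
            out.append("down")
        return tuple(out)

    def to_ms(self) -> str:
        """ms-style text block: segsites, scaled positions, 0/1 rows."""
        lines = [f"segsites: {self.n_sites}"]
        lines.append("positions: " + " ".join(
            f"{p / self.length:.6f}" for p in self.positions))
        for j in range(self.n):
            lines.append("".join(str(int(v)) for v in self.matrix[:, j]))
        return "\n".join(lines) + "\n"


class _Lineage:
    __slots__ = ("segs", "cls", "last_flush")

    def __init__(self, segs, cls, t):
        self.segs = segs          # list of (start, end, mask), disjoint, sorted
        self.cls = cls
        self.last_flush = t

    def total_len(self) -> float:
        return sum(e - s for s, e, _ in self.segs)

    def span(self, focal: float) -> tuple[float, float]:
        return (min(self.segs[0][0], focal), max(self.segs[-1][1], focal))


def _merge_seglists(a, b, full):
    """Union of two disjoint segment lists, OR-ing masks on overlap; pieces
    whose mask reaches ``full`` (local MRCA found) are dropped."""
    cuts = sorted({s for s, _, _ in a} | {e for _, e, _ in a}
                  | {s for s, _, _ in b} | {e for _, e, _ in b})
    out = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (lo + hi)
        mask = 0
        for s, e, m in a:
            if s <= mid < e:
                mask |= m
                break
        for s, e, m in b:
            if s <= mid < e:
                mask |= m
                break
        if mask == 0 or mask == full:
            continue
        if out and out[-1][1] == lo and out[-1][2] == mask:
            out[-1] = (out[-1][0], hi, mask)
        else:
            out.append((lo, hi, mask))
    return out


def _split_seglist(segs, cut):
    left = [(s, min(e, cut), m) for s, e, m in segs if s < cut]
    right = [(max(s, cut), e, m) for s, e, m in segs if e > cut]
    return left, right


class _Sim:
    """One realisation of the conditional coalescent with mutation."""

    def __init__(self, trajectory, demography, locus, n, rng):
        self.tr = trajectory
        self.dem = demography
        self.locus = locus
        self.n = n
        self.rng = rng
        self.full = (1 << n) - 1
        self.muts: list[tuple[float, int]] = []
        t0 = 0
        self.lins = [
            _Lineage([(0.0, float(locus.length), 1 << i)], DERIVED, t0)
            for i in range(n)]

    # -- mutation exposure -------------------------------------------------
    def _flush(self, lin: _Lineage, t: int) -> None:
        dt = t - lin.last_flush
        if dt > 0 and lin.segs:
            tot = lin.total_len()
            lam = self.locus.u * tot * dt
            if lam > 0:
                k = self.rng.poisson(lam)
                if k:
                    lens = np.array([e - s for s, e, _ in lin.segs])
                    seg_idx = self.rng.choice(len(lens), size=k, p=lens / lens.sum())
                    for si in seg_idx:
                        s, e, m = lin.segs[si]
                        self.muts.append((float(self.rng.uniform(s, e)), m))
        lin.last_flush = t

    # -- events ------------------------------------------------------------
    def _coalesce_groups(self, idxs, parent_count, t):
        """Assign parents uniformly among ``parent_count``; merge collisions."""
        if len(idxs) < 2 or parent_count < 1:
            return
        parents = self.rng.integers(0, parent_count, size=len(idxs))
        if len(set(parents.tolist())) == len(idxs):
            return
        groups: dict[int, list[int]] = {}
        for i, p in zip(idxs, parents):
            groups.setdefault(int(p), []).append(i)
        dead = []
        for members in groups.values():
            if len(members) < 2:
                continue
            keep = members[0]
            for other in members[1:]:
                a, b = self.lins[keep], self.lins[other]
                self._flush(a, t)
                self._flush(b, t)
                a.segs = _merge_seglists(a.segs, b.segs, self.full)
                a.last_flush = t
                dead.append(other)
            if not self.lins[keep].segs:
                dead.append(keep)
        for i in sorted(set(dead), reverse=True):
            del self.lins[i]

    def _recombine(self, i, x_t, t):
        lin = self.lins[i]
        focal = self.locus.focal_pos
        lo, hi = lin.span(focal)
        cut = self.rng.uniform(lo, hi)
        left, right = _split_seglist(lin.segs, cut)
        near, far = (left, right) if cut <= focal else (right, left)
        if not far:
            return
        new_cls = DERIVED if self.rng.random() < x_t else ANCESTRAL
        self._flush(lin, t)
        if not near:
            # breakpoint fell between the material and the focal site: the
            # whole lineage switches background
            lin.cls = new_cls
            return
        lin.segs = near
        other = _Lineage(far, new_cls, t)
        self.lins.append(other)

    # -- phases ------------------------------------------------------------
    def run(self) -> HaplotypeSet:
        counts = self.tr.counts
        age = len(counts)
        dem = self.dem
        r = self.locus.r
        focal = self.locus.focal_pos
        rng = self.rng
        # phase 1: present (t=0) back to the origin generation (t=age-1)
        for t in range(age - 1):
            c_here = int(counts[age - 1 - t])
            c_par = int(counts[age - 2 - t])
            n_par = dem.size_at(t + 1)
            der = [i for i, l in enumerate(self.lins) if l.cls == DERIVED]
            self._coalesce_groups(der, c_par, t + 1)
            anc = [i for i, l in enumerate(self.lins) if l.cls == ANCESTRAL]
            self._coalesce_groups(anc, max(2 * n_par - c_par, 1), t + 1)
            # recombination after coalescence (fixed order, thinned events)
            x_par = c_par / (2.0 * n_par)
            for i in range(len(self.lins) - 1, -1, -1):
                lin = self.lins[i]
                lo, hi = lin.span(focal)
                if rng.random() < r * (hi - lo):
                    self._recombine(i, x_par, t + 1)
            if not self.lins:
                break
        # origin: survivors of the derived class all descend from the single
        # original chromosome; transfer to the ancestral background
        t_origin = age - 1
        der = [i for i, l in enumerate(self.lins) if l.cls == DERIVED]
        if len(der) > 1:
            self._coalesce_groups(der, 1, t_origin)
        for l in self.lins:
            l.cls = ANCESTRAL
        # phase 2: unconditional coalescent, geometric fast-forward
        t = t_origin
        cap = t_origin + 2000 * dem.ancient_size
        bounds = []
        acc = 0
        for e in reversed(dem.epochs[1:]):
            acc += e.duration
            bounds.append(acc)
        while self.lins:
            k = len(self.lins)
            n_t = dem.size_at(t + 1)
            spans = [l.span(focal) for l in self.lins]
            r_rates = [r * (hi - lo) for lo, hi in spans]
            p_coal = min(k * (k - 1) / 2.0 / (2 * n_t), 1.0)
            p_tot = min(p_coal + sum(r_rates), 1.0)
            if p_tot <= 0:
                break
            gap = 1 + int(rng.geometric(p_tot)) - 1 if p_tot < 1 else 1
            nb = next((b for b in bounds if b > t), None)
            if nb is not None and t + gap > nb >= t:
                t = nb
                continue
            t += gap
            if t > cap:
                raise RuntimeError("coalescent failed to terminate")
            if rng.random() < p_coal / p_tot:
                i, j = rng.choice(k, size=2, replace=False)
                a, b = self.lins[i], self.lins[j]
                self._flush(a, t)
                self._flush(b, t)
                a.segs = _merge_seglists(a.segs, b.segs, self.full)
                a.last_flush = t
                drop = [j] if a.segs else sorted((i, j), reverse=True)
                for d in sorted(set(drop), reverse=True):
                    del self.lins[d]
            else:
                w = np.asarray(r_rates)
                i = int(rng.choice(k, p=w / w.sum()))
                self._recombine(i, 0.0, t)
        return self._emit()

    def _emit(self) -> HaplotypeSet:
        if self.muts:
            self.muts.sort()
            pos = np.array([p for p, _ in self.muts])
            matrix = np.zeros((len(self.muts), self.n), dtype=np.int8)
            for row, (_, mask) in enumerate(self.muts):
                for j in range(self.n):
                    if mask >> j & 1:
                        matrix[row, j] = 1
        else:
            pos = np.empty(0)
            matrix = np.zeros((0, self.n), dtype=np.int8)
        return HaplotypeSet(pos, matrix, self.locus.focal_pos, self.locus.length)


def simulate_haplotypes(
    trajectory: Trajectory,
    demography: DemographicModel,
    locus: LocusParams,
    n: int,
    seed: int | np.random.Generator = 0,
) -> HaplotypeSet:
    """Simulate ``n`` derived-carrying haplotypes conditional on a trajectory."""
    if n > trajectory.final_count:
        raise ValueError(
            f"n={n} exceeds the {trajectory.final_count} derived copies at present")
    if n > 62:
        raise ValueError("n > 62 haplotypes per locus is not supported")
    rng = np.random.default_rng(seed)
    return _Sim(trajectory, demography, locus, n, rng).run()


def window_probabilities(
    trajectory: Trajectory,
    demography: DemographicModel,
    locus: LocusParams,
    n: int,
    windows: WindowScheme,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte-Carlo estimate of P(L in w_j | trajectory, demography).

    Simulates ``reps`` independent haplotype sets, computes all pairwise IBS
    lengths in the direction(s) implied by the focal position, pools them
    and returns the empirical pmf over the M windows (sums to one).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    m = windows.m
    counts = np.zeros(m, dtype=np.int64)
    for _ in range(reps):
        hs = simulate_haplotypes(trajectory, demography, locus, n, rng)
        for direction in hs.directions():
            lengths = pairwise_lengths_matrix(
                hs.positions, hs.matrix, hs.focal_pos, direction)
            w = bin_lengths(lengths, windows)
            counts += np.bincount(w, minlength=m + 1)[1:]
    return counts / counts.sum()
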