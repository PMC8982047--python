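"""Pairwise identity-by-state (IBS) tract lengths around a focal allele.

The observable is ``L``: the physical distance, in one direction along the
chromosome, from a focal derived allele to the first site at which a pair of
derived-carrying haplotypes differs.  Lengths are binned into M half-open
windows ``(prev, next]`` extending away from the focal site, with the last
window open-ended; a pair with no difference within the available flank
falls in the last window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

INF_LENGTH = math.inf  # sentinel: no difference within the flank

Direction = Literal["up", "down"]


@dataclass(frozen=True)
class WindowScheme:
    """M half-open windows over bp offsets from the focal site.

    ``boundaries`` are the M-1 increasing inner edges; window j (1-based) is
    ``(boundaries[j-2], boundaries[j-1]]`` with window 1 starting after 0 and
    window M = ``(boundaries[-1], inf)``.
    """

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 1:
            raise ValueError("need at least one boundary (M >= 2)")
        if any(x <= 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be positive and strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @classmethod
    def default(cls) -> "WindowScheme":
        """Six windows with 50-kb inner edges up to 250 kb."""
        return cls((50_000.0, 100_000.0, 150_000.0, 200_000.0, 250_000.0))

    @classmethod
    def equidistant(cls, m: int, extent: float) -> "WindowScheme":
        """``m`` windows: m-1 equal windows spanning ``extent`` plus the tail."""
        if m < 2:
            raise ValueError("m must be >= 2")
        step = extent / (m - 1)
        return cls(tuple(step * i for i in range(1, m)))

    @property
    def m(self) -> int:
        return len(self.boundaries) + 1

    @property
    def span(self) -> float:
        """Flank length covered by the bounded windows."""
        return self.boundaries[-1]


def bin_length(length: float, scheme: WindowScheme) -> int:
    """Window index (1-based) for a length; half-open upper edges, so a
    length exactly on a boundary belongs to the lower window; the sentinel
    and anything beyond the last boundary land in window M."""
    if length <= 0:
        raise ValueError("IBS lengths are positive")
    if math.isinf(length):
        return len(scheme.boundaries) + 1
    # bisect over boundaries: first boundary >= length
    import bisect
    return bisect.bisect_left(scheme.boundaries, length) + 1


def bin_lengths(lengths: np.ndarray, scheme: WindowScheme) -> np.ndarray:
    """Vectorised :func:`bin_length` (1-based window indices)."""
    lengths = np.asarray(lengths, dtype=float)
    return np.searchsorted(scheme.boundaries, lengths, side="left") + 1


def pairwise_ibs_length(
    hap_a: Sequence[float] | np.ndarray,
    hap_b: Sequence[float] | np.ndarray,
    focal_pos: float,
    direction: Direction,
) -> float:
    """Distance from the focal site to the first discordant site.

    ``hap_a`` and ``hap_b`` are the positions (bp) of the sites at which
    each haplotype carries a derived (non-reference) allele; both haplotypes
    must carry the focal derived allele at ``focal_pos``.  Returns the
    absolute distance to the nearest position, in the given direction, where
    exactly one of the two haplotypes carries a derived allele, or the
    ``inf`` sentinel if none exists.
    """
    a = set(float(p) for p in np.asarray(hap_a, dtype=float))
    b = set(float(p) for p in np.asarray(hap_b, dtype=float))
    if focal_pos not in a or focal_pos not in b:
        raise ValueError("both haplotypes must carry the derived focal allele")
    diffs = a.symmetric_difference(b)
    if direction == "down":
        cand = [p - focal_pos for p in diffs if p > focal_pos]
    elif direction == "up":
        cand = [focal_pos - p for p in diffs if p < focal_pos]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return min(cand) if cand else INF_LENGTH


@dataclass
class IBSData:
    """Window-binned pairwise IBS records across loci and directions.

    ``records`` has columns (locus_id, direction, pair, length_bp, window);
    ``locus_info`` optionally carries per-locus r, u and derived counts.
    """

    records: pd.DataFrame
    scheme: WindowScheme
    locus_info: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ell(self) -> int:
        """Total record count (the bookkeeping identity's left-hand side)."""
        return len(self.records)

    def window_counts(self, locus_ids: Iterable | None = None) -> np.ndarray:
        """Counts per window (length M), optionally restricted to loci."""
        rec = self.records
        if locus_ids is not None:
            rec = rec[rec["locus_id"].isin(list(locus_ids))]
        counts = np.bincount(rec["window"].to_numpy(), minlength=self.scheme.m + 1)
        return counts[1:]

    def per_locus_window_counts(self) -> pd.DataFrame:
        """Window-count matrix indexed by locus_id (columns w1..wM)."""
        tab = (self.records.groupby(["locus_id", "window"]).size()
               .unstack(fill_value=0))
        for w in range(1, self.scheme.m + 1):
            if w not in tab.columns:
                tab[w] = 0
        tab = tab[sorted(tab.columns)]
        tab.columns = [f"w{int(c)}" for c in tab.columns]
        return tab

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# windows={','.join(str(b) for b in self.scheme.boundaries)}\n")
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "IBSData":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# windows="):
                raise ValueError("missing window-scheme header")
            scheme = WindowScheme(tuple(
                float(x) for x in header.split("=", 1)[1].split(",")))
            records = pd.read_csv(fh, sep="\t")
        return cls(records, scheme)


def expected_record_count(n_per_locus: Sequence[int], directions: int) -> int:
    """The bookkeeping identity: ell = directions * sum_loci C(n_locus, 2)."""
    return directions * sum(math.comb(int(n), 2) for n in n_per_locus)


def mask_singleton_sites(matrix: np.ndarray) -> np.ndarray:
    """Drop sites carried by exactly one of the derived-allele haplotypes.

    ``matrix`` is (sites x haplotypes) of 0/1 alleles among the derived
    carriers only; returns a boolean keep-mask over sites.
    """
    carried = matrix.sum(axis=1)
    return carried != 1


def collect_ibs(
    loci: Sequence[tuple[np.ndarray, np.ndarray, float]],
    scheme: WindowScheme,
    directions: Sequence[Direction] = ("up", "down"),
    mask_singletons: bool = False,
    locus_ids: Sequence | None = None,
    warn: callable = None,
) -> IBSData:
    """Collect window-binned IBS records across loci.

    Each locus is ``(positions, matrix, focal_pos)``: sorted site positions
    (bp), a (sites x n) 0/1 matrix over the n derived-carrying haplotypes,
    and the focal coordinate (the focal site itself must not be included as
    a segregating site).  Loci with fewer than two haplotypes are skipped
    with a warning.  Singleton masking removes, per locus, sites carried by
    exactly one of the derived haplotypes before lengths are computed.
    """
    rows = []
    ids = locus_ids if locus_ids is not None else range(len(loci))
    for locus_id, (positions, matrix, focal_pos) in zip(ids, loci):
        matrix = np.asarray(matrix)
        n = matrix.shape[1] if matrix.ndim == 2 else 0
        if n < 2:
            if warn:
                warn(f"locus {locus_id}: fewer than 2 derived haplotypes, skipped")
            continue
        positions = np.asarray(positions, dtype=float)
        if mask_singletons and len(positions):
            keep = mask_singleton_sites(matrix)
            positions, matrix = positions[keep], matrix[keep]
        for direction in directions:
            lengths = pairwise_lengths_matrix(positions, matrix, focal_pos, direction)
            windows = bin_lengths(lengths, scheme)
            pair = 0
            for i in range(n - 1):
                for j in range(i + 1, n):
                    rows.append((locus_id, direction, pair,
                                 lengths[pair], int(windows[pair])))
                    pair += 1
    records = pd.DataFrame(
        rows, columns=["locus_id", "direction", "pair", "length_bp", "window"])
    return IBSData(records, scheme)


def pairwise_lengths_matrix(
    positions: np.ndarray,
    matrix: np.ndarray,
    focal_pos: float,
    direction: Direction,
) -> np.ndarray:
    """IBS lengths for all C(n,2) haplotype pairs, vectorised.

    Returns lengths ordered as (0,1), (0,2), ..., (n-2, n-1); pairs with no
    discordant site in the direction get the ``inf`` sentinel.
    """
    n = matrix.shape[1]
    npairs = n * (n - 1) // 2
    if len(positions) == 0:
        return np.full(npairs, INF_LENGTH)
    if direction == "down":
        sel = positions > focal_pos
        dist = positions[sel] - focal_pos
    else:
        sel = positions < focal_pos
        dist = focal_pos - positions[sel]
    sub = matrix[sel]
    if sub.shape[0] == 0:
        return np.full(npairs, INF_LENGTH)
    order = np.argsort(dist, kind="stable")
    dist = dist[order]
    sub = sub[order]
    out = np.empty(npairs)
    k = 0
    for i in range(n - 1):
        xi = sub[:, i]
        diff = xi[:, None] != sub[:, i + 1:]
        first = np.argmax(diff, axis=0)
        any_diff = diff.any(axis=0)
        res = np.where(any_diff, dist[first], INF_LENGTH)
        out[k:k + n - 1 - i] = res
        k += n - 1 - i
    return out
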