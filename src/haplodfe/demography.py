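"""Piecewise-constant demographic models, selection and sampling parameters.

Time is measured in discrete generations.  A :class:`DemographicModel` is an
ordered list of epochs, most ancient first; the last epoch ends at the
present.  The most ancient epoch may be open-ended (its stated duration is
only used as a default burn-in length by the forward simulator).

The population-scaled selection coefficient ``gamma = 4*N*s`` is defined with
respect to the diploid size ``N`` of the *most ancient* epoch.  The
per-generation coefficient ``s = gamma / (4 N)`` is held constant across
epochs, so the effective scaled coefficient changes when the population size
changes (e.g. it grows 10-fold after a 10-fold expansion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence


@dataclass(frozen=True)
class Epoch:
    """One constant-size epoch: diploid size and duration in generations."""

    size: int
    duration: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"epoch size must be >= 2, got {self.size}")
        if self.duration < 1:
            raise ValueError(f"epoch duration must be >= 1, got {self.duration}")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant diploid population sizes, most ancient epoch first."""

    epochs: tuple[Epoch, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("a demographic model needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs))

    @classmethod
    def constant(cls, size: int, duration: int = 1, label: str = "") -> "DemographicModel":
        return cls((Epoch(size, duration),), label or f"constant-N{size}")

    @classmethod
    def from_epochs(cls, epochs: Sequence[tuple[int, int]], label: str = "") -> "DemographicModel":
        return cls(tuple(Epoch(s, d) for s, d in epochs), label)

    @property
    def ancient_size(self) -> int:
        """Diploid size of the most ancient epoch (defines 4Ns and theta)."""
        return self.epochs[0].size

    @property
    def recent_size(self) -> int:
        return self.epochs[-1].size

    @property
    def recent_duration(self) -> int:
        """Generations from the end of the most ancient epoch to the present."""
        return sum(e.duration for e in self.epochs[1:])

    def size_at(self, gens_before_present: int) -> int:
        """Diploid size ``gens_before_present`` generations before present.

        Generation 0 is the present.  Times older than the stated start of
        the most ancient epoch fall in the (open-ended) most ancient epoch.
        """
        t = 0
        for epoch in reversed(self.epochs):
            t += epoch.duration
            if gens_before_present < t:
                return epoch.size
        return self.epochs[0].size

    def size_trace(self, n_gens: int) -> "list[int]":
        """Sizes for generations ``n_gens-1 .. 0`` before present (oldest first)."""
        return [self.size_at(t) for t in range(n_gens - 1, -1, -1)]


@dataclass(frozen=True)
class SelectionParams:
    """Scaled selection coefficient 4Ns (ancient-epoch N) and dominance h.

    Genotype fitnesses are 1, 1+2hs, 1+2s, so at h=1/2 the heterozygote
    effect is s = gamma/(4N) (genic selection); gamma < 0 is deleterious.
    """

    gamma: float
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")

    def s(self, ancient_size: int) -> float:
        """Per-generation selection coefficient for a given ancient N."""
        return self.gamma / (4.0 * ancient_size)


@dataclass(frozen=True)
class SampleConfig:
    """Present-day sampling scheme for focal variants.

    S chromosomes are sampled; loci are retained when the derived allele's
    sample frequency lies in ``f +- tolerance``; ``n`` derived-carrying
    haplotypes per locus enter the IBS computation; ``A`` independent loci.
    """

    S: int
    f: float
    tolerance: float = 0.0
    n: int | None = None
    A: int = 1

    def __post_init__(self) -> None:
        if round(self.f * self.S) < 2:
            raise ValueError("round(f*S) must be >= 2 to form at least one pair")
        n = self.n if self.n is not None else self.target_count
        if n > round((self.f + self.tolerance) * self.S):
            raise ValueError("n exceeds the largest accepted derived sample count")
        object.__setattr__(self, "n", n)

    @property
    def target_count(self) -> int:
        return int(round(self.f * self.S))

    @property
    def count_band(self) -> tuple[int, int]:
        """Inclusive range of accepted derived sample counts."""
        lo = math.ceil((self.f - self.tolerance) * self.S - 1e-9)
        hi = math.floor((self.f + self.tolerance) * self.S + 1e-9)
        return max(lo, 1), hi

    def accepts(self, count: int) -> bool:
        lo, hi = self.count_band
        return lo <= count <= hi


@dataclass(frozen=True)
class LocusParams:
    """Per-locus mutation/recombination rates and region geometry.

    u and r are per-base per-generation rates; ``length`` is the region
    length in bp; ``focal_pos`` the coordinate of the selected site (0 for a
    left-end focal site, length/2 for a midpoint one).
    """

    u: float
    r: float
    length: int
    focal_pos: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0 or self.r < 0:
            raise ValueError("u and r must be non-negative")
        if self.length <= 0:
            raise ValueError("region length must be positive")
        if not 0 <= self.focal_pos <= self.length:
            raise ValueError("focal_pos must lie inside [0, length]")

    def theta(self, ancient_size: int) -> float:
        return 4.0 * ancient_size * self.u * self.length

    def rho(self, ancient_size: int) -> float:
        return 4.0 * ancient_size * self.r * self.length


def rescale_model(
    demography: DemographicModel,
    selection: SelectionParams,
    locus: LocusParams,
    factor: float,
    scale_time: bool = False,
) -> tuple[DemographicModel, SelectionParams, LocusParams]:
    """Rescale a model by ``factor`` keeping 4Ns, theta and rho invariant.

    Population sizes are divided by ``factor`` (rounded) while s, u and r
    are multiplied by it, which preserves the scaled parameters 4Ns,
    theta = 4Nul and rho = 4Nrl up to rounding.  Epoch durations are kept in
    generations by default; ``scale_time=True`` additionally divides them by
    ``factor`` (rounded, floored at 1) so that durations stay fixed in
    coalescent units instead.
    """
    if factor < 1:
        raise ValueError("rescaling factor must be >= 1")
    new_epochs = []
    for e in demography.epochs:
        size = int(round(e.size / factor))
        if size < 2:
            raise ValueError(
                f"factor {factor} shrinks an epoch of size {e.size} below 2")
        duration = max(1, int(round(e.duration / factor))) if scale_time else e.duration
        new_epochs.append(Epoch(size, duration))
    old_n, new_n = demography.ancient_size, new_epochs[0].size
    # keep gamma = 4Ns exact: s scales by the realized size ratio
    new_sel = replace(selection, gamma=selection.gamma)
    ratio = old_n / new_n
    new_locus = replace(locus, u=locus.u * ratio, r=locus.r * ratio)
    label = f"{demography.label}/x{factor:g}" if demography.label else f"x{factor:g}"
    return DemographicModel(tuple(new_epochs), label), new_sel, new_locus
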