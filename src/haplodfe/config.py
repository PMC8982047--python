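"""YAML run configuration: every downstream precondition is validated
before any simulation starts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .demography import DemographicModel, LocusParams, SampleConfig
from .ibs import WindowScheme


@dataclass
class RunConfig:
    demography: DemographicModel
    sample: SampleConfig
    locus: LocusParams
    scheme: WindowScheme
    grid: np.ndarray
    seed: int = 0
    ess_threshold: float = 100.0
    theta_prf: float = 100.0
    K: int = 1000
    reps: int = 100
    sim_slots: int | None = None
    tau: int = 200
    alpha_grid: tuple = ()
    beta_grid: tuple = ()
    r_strata: tuple = ()       # per-stratum r values; empty = single stratum
    mask_singletons: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(sorted(set(float(g) for g in self.grid)))
        if len(self.grid) < 1:
            raise ValueError("empty 4Ns grid")
        if self.K < 1 or self.reps < 1:
            raise ValueError("K and reps must be >= 1")
        if self.ess_threshold < 0:
            raise ValueError("ess_threshold must be non-negative")
        if self.scheme.span > min(self.locus.focal_pos or self.locus.length,
                                  self.locus.length - self.locus.focal_pos
                                  if self.locus.focal_pos < self.locus.length
                                  else self.locus.length):
            raise ValueError("window span exceeds the available flank")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dem = DemographicModel.from_epochs(
            [(int(e["size"]), int(e["duration"])) for e in raw["demography"]["epochs"]],
            label=raw["demography"].get("label", ""))
        s = raw["sample"]
        sample = SampleConfig(S=int(s["S"]), f=float(s["f"]),
                              tolerance=float(s.get("tolerance", 0.0)),
                              n=s.get("n"), A=int(s.get("A", 1)))
        l = raw["locus"]
        locus = LocusParams(u=float(l["u"]), r=float(l["r"]),
                            length=int(l["length"]),
                            focal_pos=float(l.get("focal_pos", 0.0)))
        scheme = WindowScheme(tuple(float(b) for b in raw["windows"]))
        grid = raw.get("grid", list(range(-200, 201, 5)))
        kw = {k: raw[k] for k in (
            "seed", "ess_threshold", "theta_prf", "K", "reps", "sim_slots",
            "tau", "mask_singletons") if k in raw}
        if "alpha_grid" in raw:
            kw["alpha_grid"] = tuple(raw["alpha_grid"])
        if "beta_grid" in raw:
            kw["beta_grid"] = tuple(raw["beta_grid"])
        if "r_strata" in raw:
            kw["r_strata"] = tuple(float(r) for r in raw["r_strata"])
        return cls(dem, sample, locus, scheme, np.asarray(grid, dtype=float), **kw)
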