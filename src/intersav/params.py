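"""Analysis parameters, serialised into every output for provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .aminoacids import MAX_ASA


@dataclass
class Parameters:
    """All tunable thresholds of the pipeline in one record.

    distance_cutoff
        maximum inter-atomic distance (A) defining a cross-chain
        contact; contacts are inclusive (``<=``).
    exposure_cutoff
        relative-accessibility fraction below which a residue is
        buried.
    probe_radius / n_points
        solvent probe radius (A) and lattice density for SASA.
    ddg_minor / ddg_warm / ddg_hotspot
        alanine-scan energy tier edges (kcal/mol).
    bonferroni_m
        number of comparisons for the region-pair correction
        (six pairwise region contrasts per variant category).
    """

    distance_cutoff: float = 5.0
    exposure_cutoff: float = 0.07
    probe_radius: float = 1.4
    n_points: int = 960
    ddg_minor: float = 0.5
    ddg_warm: float = 1.0
    ddg_hotspot: float = 2.0
    sift_cutoff: float = 0.10
    blosum_nonconservative: int = -1
    blosum_radical: int = -2
    grantham_nonconservative: int = 60
    grantham_radical: int = 100
    min_identity: float = 30.0
    min_coverage: float = 0.8
    bonferroni_m: int = 6
    seed: int = 0
    max_asa: dict[str, float] = field(default_factory=lambda: dict(MAX_ASA))

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.exposure_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not (self.ddg_minor < self.ddg_warm < self.ddg_hotspot):
            raise ValueError("energy tier edges must increase")

    def max_asa_for(self, aa: str) -> float:
        return self.max_asa[aa]

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "max_asa"}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_file(cls, path: str) -> "Parameters":
        """Read a flat ``key = value`` (or ``key: value``) config file."""
        kwargs: dict = {}
        numeric = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, val = (s.strip() for s in line.split(sep, 1))
                        break
                else:
                    raise ValueError(f"cannot parse config line: {line!r}")
                if key not in numeric:
                    raise KeyError(f"unknown parameter {key!r}")
                typ = numeric[key]
                kwargs[key] = int(val) if "int" in str(typ) else float(val)
        return cls(**kwargs)
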