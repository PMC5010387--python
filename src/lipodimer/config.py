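"""Pipeline configuration: one YAML file carrying every tunable.

Defaults equal the experimentally stated values; any CLI flag overrides
its config entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .density import ConversionConstants
from .labeling import LabelingYields
from .liposomes import DIMER_EXCLUSION_RADIUS_NM

__all__ = ["PipelineConfig"]

_KNOWN_KEYS = {
    "mw_protein", "mw_lipid", "sa_lipid", "recovery_factor",
    "orientation_factor", "p_cy5", "p_ns", "radius_table", "r_min_monomer",
    "r_min_dimer", "m", "temperature_k", "fix_y0", "weight_floor", "seed",
    "bias",
}


@dataclass
class PipelineConfig:
    """Validated bundle of constants, yields and fit options."""

    constants: ConversionConstants = field(default_factory=ConversionConstants)
    yields: LabelingYields = field(default_factory=LabelingYields)
    radius_table: str | None = None  # path; None -> packaged default
    r_min_monomer: float = 0.0
    r_min_dimer: float = DIMER_EXCLUSION_RADIUS_NM
    m: int = 5
    temperature_k: float = 298.0
    fix_y0: float | None = None
    weight_floor: float = 1e-6
    seed: int | None = None
    bias: float | None = None  # reserved hook; not used by any stage

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.r_min_monomer < 0 or self.r_min_dimer < 0:
            raise ValueError("exclusion radii must be non-negative")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be strictly positive")
        if self.weight_floor <= 0:
            raise ValueError("weight_floor must be strictly positive")
        if self.fix_y0 is not None and not 0 <= self.fix_y0 < 1:
            raise ValueError("fix_y0 must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        const_kwargs = {
            k: raw[k]
            for k in ("mw_protein", "mw_lipid", "sa_lipid",
                      "recovery_factor", "orientation_factor")
            if k in raw
        }
        yield_kwargs = {k: raw[k] for k in ("p_cy5", "p_ns") if k in raw}
        other = {
            k: raw[k]
            for k in raw
            if k not in const_kwargs and k not in yield_kwargs
        }
        return cls(
            constants=ConversionConstants(**const_kwargs),
            yields=LabelingYields(**yield_kwargs),
            **other,
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    def radius_distribution(self):
        from .liposomes import RadiusDistribution, default_radius_distribution

        if self.radius_table is None:
            return default_radius_distribution()
        return RadiusDistribution.from_file(self.radius_table)
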