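"""Model parameters shared by the read simulator and the alignment models.

Defaults are the parameter set used for designing the shipped seed
families: SNP probability 0.0085, indel probability 0.0015, reading-error
probability rising from 0.01 at the start of the read to 0.1 at its end,
and a periodic reading-error probability of 0.02.  The submodel-switching
probability ``p_switch`` controls how fast period-5 error phases
accumulate along a read; it is a free parameter of the reading-error
model (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    p_snp: float = 0.0085
    p_indel: float = 0.0015
    p_err_start: float = 0.01
    p_err_end: float = 0.1
    p_err_periodic: float = 0.02
    p_switch: float = 0.05
    #: Probability that a color indel is preceded by a color mismatch.
    p_indel_pre_mismatch: float = 0.75
    #: Target lag-5 quality correlation injected by the read simulator.
    quality_lag5_rho: float = 0.6

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.p_snp + self.p_indel > 1.0:
            raise ValueError("p_snp + p_indel must not exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"model config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
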