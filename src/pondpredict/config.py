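"""Run configuration: every analysis constant lives here, never in operations."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError

ALL_MODELS = ("COL_wd", "GAM_a", "COL_ANa", "GAM_w", "COL_ANw", "COL_MAXg", "COL_MAXlin")


@dataclass
class RunConfig:
    """Defaults mirror the published analysis constants."""

    band_map: dict = field(default_factory=lambda: {"green": 1, "nir": 2, "mir": 3})
    reflectance_scale: float = 1.0
    mndwi_cut: float = 0.0           # water candidacy: MNDWI strictly above this
    nir_salt_cut: float = 0.4        # salt crust at and above this NIR reflectance
    neighborhood: float = 0.7        # mean +/- 70% state breaks
    gam_k: int = 8
    gam_cyclic: bool = False
    gam_w_fit_zeros: bool = True
    models: tuple = ALL_MODELS
    n_boot: int = 10_000
    seed: int = 42
    cut: float = 0.90
    exclude_ponds: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "exclude_ponds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["exclude_ponds"] = list(self.exclude_ponds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
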