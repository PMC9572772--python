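"""Run configuration and result provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import constants

__all__ = ["RunConfig", "sha256_digest", "write_result_json"]


@dataclass(frozen=True)
class RunConfig:
    """All cross-stage knobs in one serializable record.

    Defaults: 298 K (25 C on the T = degC + 273 convention), hc =
    1239.84 eV.nm, ICH factors (3.3, 10), RDG density floor 1e-10 a.u.,
    Popelier rho-range [0.002, 0.040] a.u.
    """

    temperature_K: float = constants.DEFAULT_TEMPERATURE_K
    hc_ev_nm: float = constants.HC_EV_NM
    ich_factors: tuple[float, float] = (constants.ICH_LOD_FACTOR,
                                        constants.ICH_LOQ_FACTOR)
    rho_floor: float = constants.RHO_FLOOR
    popelier_range: tuple[float, float] = constants.POPELIER_RHO_RANGE
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.rho_floor <= 0:
            raise ValueError("rho_floor must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ich_factors"] = list(self.ich_factors)
        d["popelier_range"] = list(self.popelier_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML; keyword overrides (e.g. CLI flags) win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("ich_factors", "popelier_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items()
                                if v is not None})


def sha256_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_result_json(path: str | Path, stage: str, payload: dict,
                      config: RunConfig,
                      input_paths: dict[str, str | Path] | None = None) -> dict:
    """Write a result record embedding the config and input digests.

    Timestamps are deliberately omitted so identical inputs + config + seed
    reproduce byte-identical files.
    """
    record = {
        "stage": stage,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": sha256_digest(p)}
                   for name, p in (input_paths or {}).items()},
        "result": payload,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return record
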