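"""YAML configuration: schema validation, defaults, run manifests.

The pipeline exchanges one YAML config with four blocks (``cohort``,
``physics``, ``aerosol``, ``engine``, ``analysis``).  Unknown keys are
rejected with their dotted location; omitted keys fall back to packaged
defaults.  A run manifest (JSON) records everything needed to reproduce
a run bit-identically: config hash, master seed, particle count,
package version and file paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .aerosol import PRESETS, AerosolSpec
from .airways import default_acinus, default_morphometry
from .cohort import CohortConfig
from .engine import EngineConfig
from .physics import PhysicsConstants

__all__ = ["PipelineConfig", "load_config", "config_hash", "RunManifest"]


_DEFAULTS: dict = {
    "cohort": {
        "group_sizes": dict,  # filled from CohortConfig defaults
        "intra_subject_cv": 0.08,
        "latent_corr": 0.6,
    },
    "physics": {
        "viscosity_air": 1.81e-5,
        "mean_free_path_um": 0.066,
        "gravity": 9.81,
        "temperature": 310.0,
    },
    "aerosol": {"devices": {}},
    "engine": {
        "n_particles": 100_000,
        "v_ref_l": 4.8,
        "exhalation_multiplier": 1.0,
        "r_alv_cm": 0.014,
        "et_a": 1.1e-4,
        "et_b": 1.4,
    },
    "analysis": {"loa_multiplier": 1.96},
}


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig
    engine: EngineConfig
    aerosols: dict[str, AerosolSpec]
    loa_multiplier: float = 1.96
    raw: dict = field(default_factory=dict, compare=False)


class ConfigError(ValueError):
    pass


def _check_keys(data: dict, allowed: dict, path: str = "") -> None:
    for key, value in data.items():
        loc = f"{path}{key}"
        if key not in allowed:
            raise ConfigError(f"unknown config key: {loc!r} "
                              f"(allowed here: {sorted(allowed)})")
        if isinstance(allowed[key], dict) and allowed[key] and not isinstance(allowed[key], type):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {loc!r} must be a mapping")
            _check_keys(value, allowed[key], loc + ".")


_SCHEMA: dict = {
    "cohort": {"group_sizes": {}, "intra_subject_cv": {}, "latent_corr": {},
               "seed": {}},
    "physics": {"viscosity_air": {}, "mean_free_path_um": {}, "gravity": {},
                "temperature": {}},
    "aerosol": {"devices": {}},
    "engine": {"n_particles": {}, "v_ref_l": {}, "exhalation_multiplier": {},
               "r_alv_cm": {}, "et_a": {}, "et_b": {}, "et_v_ml": {},
               "et_r_cm": {}, "n_time_grid": {}},
    "analysis": {"loa_multiplier": {}},
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; ``None``/empty file = defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    _check_keys(data, _SCHEMA)

    phys = data.get("physics", {})
    constants = PhysicsConstants(
        viscosity_air=phys.get("viscosity_air", 1.81e-5),
        mean_free_path_um=phys.get("mean_free_path_um", 0.066),
        gravity=phys.get("gravity", 9.81),
        temperature=phys.get("temperature", 310.0),
    )
    eng = data.get("engine", {})
    engine = EngineConfig(
        n_particles=int(eng.get("n_particles", 100_000)),
        v_ref_l=eng.get("v_ref_l", 4.8),
        exhalation_multiplier=eng.get("exhalation_multiplier", 1.0),
        r_alv_cm=eng.get("r_alv_cm", 0.014),
        et_a=eng.get("et_a", 1.1e-4),
        et_b=eng.get("et_b", 1.4),
        et_v_ml=eng.get("et_v_ml", 50.0),
        et_r_cm=eng.get("et_r_cm", 1.0),
        n_time_grid=int(eng.get("n_time_grid", 1024)),
        morphometry=default_morphometry(),
        acinus=default_acinus(),
        constants=constants,
    )
    coh = data.get("cohort", {})
    cohort = CohortConfig(
        group_sizes=dict(coh.get("group_sizes") or CohortConfig().group_sizes),
        intra_subject_cv=coh.get("intra_subject_cv", 0.08),
        latent_corr=coh.get("latent_corr", 0.6),
        seed=int(coh.get("seed", 0)),
    )
    aerosols = dict(PRESETS)
    for name, spec_dict in (data.get("aerosol", {}).get("devices") or {}).items():
        base = aerosols.get(name)
        merged = {**(base.to_dict() if base else {"label": name}), **spec_dict}
        aerosols[name] = AerosolSpec.from_dict(merged)
    return PipelineConfig(
        cohort=cohort, engine=engine, aerosols=aerosols,
        loa_multiplier=data.get("analysis", {}).get("loa_multiplier", 1.96),
        raw=data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the effective configuration."""
    payload = {
        "cohort": {"group_sizes": cfg.cohort.group_sizes,
                   "intra_subject_cv": cfg.cohort.intra_subject_cv,
                   "latent_corr": cfg.cohort.latent_corr,
                   "seed": cfg.cohort.seed},
        "engine": {k: v for k, v in asdict(cfg.engine).items()
                   if isinstance(v, (int, float, str))},
        "aerosols": {k: v.to_dict() for k, v in sorted(cfg.aerosols.items())},
        "analysis": {"loa_multiplier": cfg.loa_multiplier},
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    n_particles: int
    package_version: str
    created_utc: str
    inputs: dict
    outputs: dict

    @classmethod
    def create(cls, cfg: PipelineConfig, seed: int, n_particles: int,
               inputs: dict, outputs: dict) -> "RunManifest":
        from . import __version__
        return cls(config_hash=config_hash(cfg), master_seed=seed,
                   n_particles=n_particles, package_version=__version__,
                   created_utc=datetime.now(timezone.utc).isoformat(),
                   inputs=inputs, outputs=outputs)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
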