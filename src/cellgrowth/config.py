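"""YAML pipeline configuration.

One config dialect (YAML) drives the end-to-end workflow.  The schema is
validated strictly: unknown keys at any level are rejected so typos fail
fast rather than silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import (
    FixedConstants,
    ParameterSet,
    default_synthetic_constants,
    default_synthetic_parameters,
)
from .synthetic import NOISE_GRID, ExperimentalDesign, default_design


class ConfigError(ValueError):
    pass


_SCHEMA: dict = {
    "model": {"required_substrates", "selected", "candidates"},
    "parameters": {"beta", "delta", "V_g", "cbar_g", "K_o", "K_g", "K_l"},
    "constants": {"V_o", "cbar_o", "n_max", "lactate_sign"},
    "design": {
        "environments", "seedings", "replicates", "sampling_period_h",
        "first_sample_h", "last_sample_h", "cl0",
    },
    "noise": {"epsilon", "seed"},
    "split": {"fractions", "seed"},
    "fit": {
        "n_starts", "bounds", "stage1_iters", "stage1_step", "n_refine",
        "prescreen", "fd_step", "refine_maxiter", "refine_min_sep",
        "polish_n", "polish_maxfev", "log_loss", "adam_beta1", "adam_beta2",
        "weight_mode",
    },
    "identifiability": {"alpha", "convention", "n_grid", "reopt_maxiter"},
    "gsa": {"ranges", "n_base", "n_boot", "output_time_h", "enabled"},
    "mbdep": {
        "enabled", "periods_h", "noise_levels", "n_repeats", "fit",
        "tolerance_ratio",
    },
    "refreshment": {"enabled", "periods_days", "horizon_days", "reset_targets"},
    "dataset": {"path"},
    "seed": None,
}


def _check_keys(raw: dict) -> None:
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    for key, allowed in _SCHEMA.items():
        if allowed is None or key not in raw:
            continue
        section = raw[key]
        if not isinstance(section, dict):
            raise ConfigError(f"config section {key!r} must be a mapping")
        bad = set(section) - allowed
        if bad:
            raise ConfigError(f"unknown keys in section {key!r}: {sorted(bad)}")


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys(self.raw)

    # ---- section accessors -------------------------------------------
    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}) or {})

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def required_substrates(self) -> set[str]:
        return set(self.section("model").get("required_substrates",
                                             ["oxygen", "glucose"]))

    def parameters(self) -> ParameterSet:
        sec = self.section("parameters")
        if not sec:
            return default_synthetic_parameters()
        base = asdict(default_synthetic_parameters())
        base.update({k: float(v) for k, v in sec.items() if v is not None})
        return ParameterSet(**base)

    def constants(self) -> FixedConstants:
        sec = self.section("constants")
        if not sec:
            return default_synthetic_constants()
        base = asdict(default_synthetic_constants())
        for k, v in sec.items():
            base[k] = int(v) if k == "lactate_sign" else float(v)
        return FixedConstants(**base)

    def design(self) -> ExperimentalDesign:
        sec = self.section("design")
        base = default_design()
        if not sec:
            return base
        kwargs = {
            "environments": tuple(
                tuple(map(float, e)) for e in sec.get(
                    "environments", base.environments)
            ),
            "seedings": tuple(map(float, sec.get("seedings", base.seedings))),
            "replicates": int(sec.get("replicates", base.replicates)),
            "sampling_period_h": float(
                sec.get("sampling_period_h", base.sampling_period_h)),
            "first_sample_h": float(sec.get("first_sample_h", base.first_sample_h)),
            "last_sample_h": float(sec.get("last_sample_h", base.last_sample_h)),
            "cl0": float(sec.get("cl0", base.cl0)),
        }
        return ExperimentalDesign(**kwargs)

    def noise(self) -> tuple[float, int]:
        sec = self.section("noise")
        eps = float(sec.get("epsilon", 0.1))
        if eps < 0:
            raise ConfigError("noise.epsilon must be non-negative")
        return eps, int(sec.get("seed", self.seed))

    def split(self) -> tuple[tuple[float, float, float], int]:
        sec = self.section("split")
        fractions = tuple(map(float, sec.get("fractions", (0.6, 0.2, 0.2))))
        return fractions, int(sec.get("seed", self.seed))

    def fit_options(self) -> dict:
        sec = self.section("fit")
        sec.setdefault("n_starts", 100)
        return sec

    def mbdep(self) -> dict:
        sec = self.section("mbdep")
        sec.setdefault("enabled", False)
        sec.setdefault("periods_h", [24.0, 48.0])
        sec.setdefault("noise_levels", list(NOISE_GRID))
        sec.setdefault("n_repeats", 2)
        return sec

    def refreshment(self) -> dict:
        sec = self.section("refreshment")
        sec.setdefault("enabled", False)
        sec.setdefault("periods_days", list(range(2, 25, 2)))
        sec.setdefault("horizon_days", 43.0)
        return sec

    def gsa(self) -> dict:
        sec = self.section("gsa")
        sec.setdefault("enabled", True)
        sec.setdefault("n_base", 512)
        sec.setdefault("n_boot", 100)
        sec.setdefault("output_time_h", 114.0)
        return sec

    def identifiability(self) -> dict:
        sec = self.section("identifiability")
        sec.setdefault("alpha", 0.95)
        sec.setdefault("convention", "likelihood_ratio")
        sec.setdefault("n_grid", 20)
        return sec

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig({})
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig(raw)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.raw, sort_keys=True))
    return path
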