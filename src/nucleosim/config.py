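"""Configuration schemas, named scenario presets and YAML loading.

A model configuration describes the lattice, the potentials and the rate
constants; a protocol configuration describes replicas, time grid and
seed.  Unknown keys are rejected and all violations are reported together.

Presets bundle the parameter combinations of the main simulated scenarios:

==================  ============================================================
``barrier_only``    triangular promoter barrier, no enzymes (statistical
                    positioning)
``barrier_spacer``  barrier + spacer enzymes k = 0.16/s (mouse-active-like)
``yeast_like``      barrier + positioning well (-2 k_B T on [0, 30]) + spacer
                    enzymes k = 0.16/s
``yeast_slow``      as ``yeast_like`` with k = 0.08/s (less active genes)
``pol2_exchange``   barrier + spacer enzymes + explicit histone exchange at
                    r_const = 0.1/s (fast Pol II-driven turnover)
``intermediate``    weakened barrier (2 k_B T) + k = 0.12/s
``density_078``     barrier + spacer enzymes at target density 0.78
==================  ============================================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .lattice import EnergyField, LatticeSpec, PairPotential, make_barrier, make_positioning
from .kinetics import KineticModel, SimulationProtocol

__all__ = [
    "ModelConfig",
    "ProtocolConfig",
    "ConfigError",
    "load_config",
    "build_model",
    "build_protocol",
    "PRESETS",
    "preset_config",
]


class ConfigError(ValueError):
    """Invalid configuration; message lists every violation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BarrierConfig(_Strict):
    center_offset: int = -150
    half_width: int = Field(150, gt=0)
    height: float = Field(25.0, ge=0)


class PositioningConfig(_Strict):
    start_offset: int = 0
    end_offset: int = 30
    depth: float = Field(-2.0, le=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.start_offset >= self.end_offset:
            raise ValueError("start_offset must be < end_offset")
        return self


class LatticeConfig(_Strict):
    length_bp: int = Field(14700, gt=0)
    tss_index: int = Field(7350, ge=0)
    footprint_bp: int = Field(147, gt=0)


class ModelConfig(_Strict):
    """Flat model description mapping onto `KineticModel`."""

    lattice: LatticeConfig = LatticeConfig()
    binding_energy_kBT: float = -42.0
    affinity_profile_tsv: Optional[str] = None
    barrier: Optional[BarrierConfig] = BarrierConfig()
    positioning: Optional[PositioningConfig] = None
    D_bp2_per_s: float = Field(1.0, ge=0)
    step_bp: float = Field(1.0, gt=0)
    enzyme_rate_per_s: float = Field(0.0, ge=0)
    enzyme_range_bp: int = Field(332, gt=0)
    r_const_per_s: float = Field(0.0, ge=0)
    mu_kBT: float = 0.0
    use_effective_attraction: bool = False
    target_density: float = Field(0.88, gt=0, lt=1)


class ProtocolConfig(_Strict):
    n_replicas: int = Field(1, ge=1)
    t_end_s: float = Field(5000.0, gt=0)
    burn_in_s: float = Field(2500.0, ge=0)
    sample_interval_s: float = Field(2.0, gt=0)
    initial_n_nucleosomes: Optional[int] = None
    seed: int = 0


class RunConfig(_Strict):
    model: ModelConfig = ModelConfig()
    protocol: ProtocolConfig = ProtocolConfig()


PRESETS: dict[str, dict] = {
    "barrier_only": {
        "model": {"barrier": {}, "enzyme_rate_per_s": 0.0}},
    "barrier_spacer": {
        "model": {"barrier": {}, "enzyme_rate_per_s": 0.16,
                  "use_effective_attraction": True}},
    "yeast_like": {
        "model": {"barrier": {}, "positioning": {}, "enzyme_rate_per_s": 0.16,
                  "use_effective_attraction": True}},
    "yeast_slow": {
        "model": {"barrier": {}, "positioning": {}, "enzyme_rate_per_s": 0.08,
                  "use_effective_attraction": True}},
    "pol2_exchange": {
        "model": {"barrier": {}, "enzyme_rate_per_s": 0.16,
                  "r_const_per_s": 0.1}},
    "intermediate": {
        "model": {"barrier": {"height": 2.0}, "enzyme_rate_per_s": 0.12,
                  "use_effective_attraction": True}},
    "density_078": {
        "model": {"barrier": {}, "enzyme_rate_per_s": 0.16,
                  "use_effective_attraction": True, "target_density": 0.78}},
}


def preset_config(name: str, **overrides) -> RunConfig:
    """Named scenario preset as a validated RunConfig."""
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    payload = {k: dict(v) for k, v in PRESETS[name].items()}
    for key, val in overrides.items():
        payload.setdefault("model", {})
        payload[key] = val
    try:
        return RunConfig(**payload)
    except ValidationError as exc:  # pragma: no cover - presets are valid
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML model+protocol configuration.

    Unknown keys are rejected; all field violations are reported in one
    error message.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from exc


def build_field(cfg: ModelConfig) -> EnergyField:
    lattice = LatticeSpec(
        length_bp=cfg.lattice.length_bp,
        tss_index=cfg.lattice.tss_index,
        footprint_bp=cfg.lattice.footprint_bp,
    )
    barrier = positioning = None
    if cfg.barrier is not None:
        barrier = make_barrier(
            lattice, cfg.barrier.center_offset, cfg.barrier.half_width,
            cfg.barrier.height,
        )
    if cfg.positioning is not None:
        positioning = make_positioning(
            lattice, cfg.positioning.start_offset, cfg.positioning.end_offset,
            cfg.positioning.depth,
        )
    if cfg.affinity_profile_tsv is not None:
        import pandas as pd

        df = pd.read_csv(cfg.affinity_profile_tsv, sep="\t")
        site = np.asarray(df["energy_kBT"], dtype=np.float64)
        if site.size != lattice.length_bp:
            raise ConfigError(
                f"affinity profile has {site.size} rows, lattice needs "
                f"{lattice.length_bp}"
            )
        return EnergyField(site, barrier, positioning, lattice)
    return EnergyField.uniform(
        lattice, cfg.binding_energy_kBT, barrier, positioning
    )


def build_model(cfg: ModelConfig, pair: PairPotential | None = None) -> KineticModel:
    """KineticModel from a config; ``pair`` may carry a calibrated u_eff."""
    field = build_field(cfg)
    if pair is None:
        pair = PairPotential(hard_core_bp=field.lattice.footprint_bp)
    return KineticModel(
        field=field,
        pair=pair,
        D=cfg.D_bp2_per_s,
        step_bp=cfg.step_bp,
        enzyme_rate=cfg.enzyme_rate_per_s,
        enzyme_range_bp=cfg.enzyme_range_bp,
        r_const=cfg.r_const_per_s,
        mu=cfg.mu_kBT,
    )


def build_protocol(cfg: ProtocolConfig) -> SimulationProtocol:
    return SimulationProtocol(
        n_replicas=cfg.n_replicas,
        t_end=cfg.t_end_s,
        burn_in=cfg.burn_in_s,
        sample_interval=cfg.sample_interval_s,
        initial_n_nucleosomes=cfg.initial_n_nucleosomes,
        seed=cfg.seed,
    )


def barrier_free_length(cfg: ModelConfig) -> int:
    """Length of DNA outside the barrier support (density denominator)."""
    if cfg.barrier is None:
        return cfg.lattice.length_bp
    return cfg.lattice.length_bp - 2 * cfg.barrier.half_width
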