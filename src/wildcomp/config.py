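"""Pipeline configuration: every stage threshold with its published default.

Config files are TOML; unknown keys are rejected so a typo cannot silently
fall back to a default.  Every CLI flag overrides its config key.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields

from .io import WildcompError
from .simulate import SimulationSpec


class ConfigError(WildcompError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "wildcomp_out"
    # homology / placement
    min_identity: float = 0.80
    min_coverage: float = 0.50
    homolog_min_score: int = 50
    homolog_min_identity: float = 0.60
    # synteny
    min_block_genes: int = 3
    max_gap: int = 5
    allow_inversions: bool = True
    min_scaffold_len: int = 0
    # PAV confirmation
    covered_site_min_depth: int = 1
    max_covered_fraction: float = 0.50
    # variants
    max_substitutions: int = 2
    snv_min_depth: int = 4
    min_alt_fraction: float = 0.9
    window: int = 10_000_000
    # expression
    fold_threshold: float = 2.0
    padj_threshold: float = 0.01
    # clocks
    ltr_rate: float = 1.3e-8
    ks_rate: float = 6.5e-9
    # simulator stage parameters
    simulation: SimulationSpec = field(default_factory=SimulationSpec)

    def __post_init__(self):
        checks = [
            (0 < self.min_identity <= 1, "min_identity in (0, 1]"),
            (0 < self.min_coverage <= 1, "min_coverage in (0, 1]"),
            (self.min_block_genes >= 1, "min_block_genes >= 1"),
            (self.max_gap >= 1, "max_gap >= 1"),
            (self.max_substitutions >= 0, "max_substitutions >= 0"),
            (self.snv_min_depth >= 1, "snv_min_depth >= 1"),
            (0 < self.min_alt_fraction <= 1, "min_alt_fraction in (0, 1]"),
            (self.window > 0, "window > 0"),
            (self.fold_threshold >= 1, "fold_threshold >= 1"),
            (0 < self.padj_threshold <= 1, "padj_threshold in (0, 1]"),
            (self.ltr_rate > 0 and self.ks_rate > 0, "clock rates > 0"),
            (0 <= self.max_covered_fraction <= 1, "max_covered_fraction in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"configuration out of domain: {msg}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d


def _build(data: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    sim_data = dict(data.pop("simulation", {}))
    sim_known = {f.name for f in fields(SimulationSpec)}
    sim_unknown = set(sim_data) - sim_known
    if sim_unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
    for key in ("ltr_ages", "tissues", "pericentromere_interval"):
        if key in sim_data:
            sim_data[key] = tuple(sim_data[key])
    seed = data.get("seed")
    if seed is not None and "seed" not in sim_data:
        sim_data["seed"] = seed
    try:
        return PipelineConfig(simulation=SimulationSpec(**sim_data), **data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str, **overrides) -> PipelineConfig:
    """Load a TOML config file; keyword overrides win over file values."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return _build(data)


def default_config(**overrides) -> PipelineConfig:
    return _build({k: v for k, v in overrides.items() if v is not None})
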