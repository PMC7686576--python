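"""Pipeline configuration: YAML schema, validation, defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    q_cutoff: float = 0.05
    n_top_atac: int = 5000
    n_top_rna: int = 500
    n_pc_loading: int = 500
    max_dist: float = 10_000
    k_min: int = 1
    k_max: int = 8
    gap_b: int = 50
    n_perm: int = 10_000
    min_cpm: float = 1.0
    min_cpm_samples: int = 2
    min_consensus_samples: int = 2
    merge_frac: float = 0.5

    def validate(self) -> None:
        for name in ("n_top_atac", "n_top_rna", "n_pc_loading", "gap_b", "n_perm",
                     "min_cpm_samples", "min_consensus_samples"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"thresholds.{name} must be positive")
        if not 0 < self.q_cutoff < 1:
            raise ConfigError("thresholds.q_cutoff must lie in (0, 1)")
        if self.k_min < 1 or self.k_max <= self.k_min:
            raise ConfigError("need 1 <= k_min < k_max")


@dataclass
class InputPaths:
    sample_sheet: str
    peaks_dir: str | None = None
    insertions_dir: str | None = None
    atac_counts: str | None = None
    rna_counts: str | None = None
    genes: str | None = None
    motifs: str | None = None
    gene_sets: str | None = None

    def validate(self) -> None:
        if self.peaks_dir is None and self.atac_counts is None:
            raise ConfigError("inputs need peaks_dir and/or atac_counts")
        for name in dataclasses.fields(self):
            val = getattr(self, name.name)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"inputs.{name.name}: no such path {val!r}")


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    simulate: SimConfig | None = None
    inputs: InputPaths | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be given")
        self.thresholds.validate()
        if self.simulate is not None:
            self.simulate.validate()
        else:
            self.inputs.validate()


def _build(cls, raw: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**raw)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a pipeline YAML config (hard failure on unknown keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {"seed", "output_dir", "simulate", "inputs", "thresholds"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("'seed' is required: every run must be reproducible")
    if "output_dir" not in raw:
        raise ConfigError("'output_dir' is required")
    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        sim_raw.setdefault("seed", int(raw["seed"]))
        for key in ("lineages", "subsets", "lib_size_range", "rna_lib_size_range",
                    "peak_width_range"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = _build(SimConfig, sim_raw, "simulate")
    inputs = None
    if "inputs" in raw and raw["inputs"] is not None:
        inputs = _build(InputPaths, dict(raw["inputs"]), "inputs")
    thresholds = _build(Thresholds, dict(raw.get("thresholds") or {}), "thresholds")
    cfg = PipelineConfig(
        seed=int(raw["seed"]), output_dir=str(raw["output_dir"]),
        simulate=sim, inputs=inputs, thresholds=thresholds,
    )
    cfg.validate()
    return cfg
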