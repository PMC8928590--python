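"""Pipeline configuration: YAML loading, validation, defaults.

A config file has up to five sections (all optional):

``simulate``   — SimulationConfig fields; presence enables the simulate stage.
``inputs``     — paths to pre-existing inputs (vcfs: list of
                 {path, sample_id, group}; coverage, chrom_sizes, repeats,
                 segdup_pairs, annotation, qtl_bed, term_map).
``filter``     — FilterPolicy fields (min_len, max_len, coverage_fraction,
                 secondary_sr_min, secondary_pe_min).
``enrichment`` — n_iter (default 1000), metrics, classes, flank_sizes.
``positional`` — terminal_frac (default 0.05), window, bin_width.
``sharing``    — min_overlap_bp, reciprocal.

Unknown keys anywhere are errors, not warnings, and all validation errors
are collected and reported at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .simulate import SimulationConfig
from .variants import FilterPolicy

__all__ = ["ConfigError", "PipelineConfig", "validate_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  - " + "\n  - ".join(errors))


@dataclass
class EnrichmentParams:
    n_iter: int = 1000
    metrics: list[str] = field(
        default_factory=lambda: ["avg_length", "length_pct", "count_per_mb"]
    )
    classes: list[str] | None = None
    flank_sizes: list[int] = field(default_factory=lambda: [5000, 20000])


@dataclass
class PositionalParams:
    terminal_frac: float = 0.05
    window: int = 5_000_000
    bin_width: float = 0.05


@dataclass
class SharingParams:
    min_overlap_bp: int = 1
    reciprocal: float = 0.0


@dataclass
class InputPaths:
    vcfs: list[dict[str, str]] = field(default_factory=list)
    coverage: str | None = None
    chrom_sizes: str | None = None
    repeats: str | None = None
    segdup_pairs: str | None = None
    annotation: str | None = None
    qtl_bed: str | None = None
    term_map: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "spermcnv_out"
    simulate: SimulationConfig | None = None
    inputs: InputPaths = field(default_factory=InputPaths)
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    positional: PositionalParams = field(default_factory=PositionalParams)
    sharing: SharingParams = field(default_factory=SharingParams)


def _build_section(cls, data: dict, section: str, errors: list[str]):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        errors.append(f"{section}: unknown keys {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline YAML; raise ConfigError listing ALL problems."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"not parseable as YAML: {exc}"]) from exc
    if not isinstance(data, dict):
        raise ConfigError(["top level of the config must be a mapping"])

    errors: list[str] = []
    top_known = {"seed", "out_dir", "simulate", "inputs", "filter",
                 "enrichment", "positional", "sharing"}
    unknown = set(data) - top_known
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")

    cfg = PipelineConfig()
    if "seed" in data:
        if not isinstance(data["seed"], int):
            errors.append("seed must be an integer")
        else:
            cfg.seed = data["seed"]
    if "out_dir" in data:
        cfg.out_dir = str(data["out_dir"])

    if isinstance(data.get("simulate"), dict):
        sim = dict(data["simulate"])
        for key in ("chrom_length_range", "event_length_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        cfg.simulate = _build_section(SimulationConfig, sim, "simulate", errors)
    elif "simulate" in data and data["simulate"] is not None:
        errors.append("simulate section must be a mapping")

    if isinstance(data.get("inputs"), dict):
        built = _build_section(InputPaths, data["inputs"], "inputs", errors)
        if built is not None:
            cfg.inputs = built
            seen: set[str] = set()
            dupes: set[str] = set()
            for entry in built.vcfs:
                if not isinstance(entry, dict) or not {"path", "sample_id", "group"} <= set(entry):
                    errors.append(
                        "inputs.vcfs entries need path, sample_id and group keys"
                    )
                    continue
                sid = entry["sample_id"]
                (dupes if sid in seen else seen).add(sid)
            if dupes:
                errors.append(f"duplicate sample IDs in inputs.vcfs: {sorted(dupes)}")
    elif "inputs" in data and data["inputs"] is not None:
        errors.append("inputs section must be a mapping")

    for section, cls, attr in [
        ("filter", FilterPolicy, "filter"),
        ("enrichment", EnrichmentParams, "enrichment"),
        ("positional", PositionalParams, "positional"),
        ("sharing", SharingParams, "sharing"),
    ]:
        if isinstance(data.get(section), dict):
            built = _build_section(cls, data[section], section, errors)
            if built is not None:
                setattr(cfg, attr, built)
        elif section in data and data[section] is not None:
            errors.append(f"{section} section must be a mapping")

    if cfg.enrichment.n_iter < 1:
        errors.append("enrichment.n_iter must be >= 1")
    if not 0.0 < cfg.positional.terminal_frac < 0.5:
        errors.append("positional.terminal_frac must be in (0, 0.5)")
    if cfg.simulate is None and not cfg.inputs.vcfs:
        errors.append("either a simulate section or inputs.vcfs is required")

    if errors:
        raise ConfigError(errors)
    return cfg
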