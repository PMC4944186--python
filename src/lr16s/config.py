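"""Run configuration: one YAML-shaped tree that fully determines a run.

Every threshold defaults to the study's value (97% OTU identity, Q20,
75% joined/retained length, 80% control span, |log2 FC| > 1, singleton
discard).  A serialized config plus its seed determines all pipeline
outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Optional

import yaml

from .synth import (
    DEFAULT_PRIMER_SET,
    ErrorProfile,
    PrimerPair,
    PrimerSet,
)


class ConfigError(ValueError):
    pass


@dataclass
class ReferenceConfig:
    n_genera: int = 4
    species_per_genus: int = 3
    length: int = 1500
    per_region_divergence: float | dict[str, float] = 0.02
    between_genus_divergence: float = 0.05


@dataclass
class LongReadConfig:
    n_reads: int = 400
    p_sub: float = 0.090
    p_ins: float = 0.064
    p_del: float = 0.050
    p_concat: float = 0.02

    @property
    def profile(self) -> ErrorProfile:
        return ErrorProfile(self.p_sub, self.p_ins, self.p_del)


@dataclass
class ControlConfig:
    n_reads: int = 300
    length: int = 1400


@dataclass
class ShortReadConfig:
    n_pairs: int = 3000
    read_len: int = 250
    q_high: int = 38
    q_low: int = 10
    p_lowq_tail: float = 0.10


@dataclass
class Thresholds:
    otu_identity: float = 0.97
    quality_q: int = 20
    min_retained_frac: float = 0.75
    min_joined_frac: float = 0.75
    min_overlap: int = 10
    max_mismatch_frac: float = 0.10
    min_ref_span: float = 0.80
    min_query_cover: float = 0.50
    log2fc_threshold: float = 1.0
    min_reads_per_taxon: int = 2


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    long_reads: LongReadConfig = field(default_factory=LongReadConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    short_reads: ShortReadConfig = field(default_factory=ShortReadConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    community_alpha: float = 1.5  # Dirichlet concentration for drawn weights
    rarefy_depth: Optional[int] = 2000
    regions_taxon_pair: Optional[list[str]] = None
    primers: PrimerSet = field(default_factory=lambda: DEFAULT_PRIMER_SET)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("field 'seed' must be an integer")
        if not (0 < self.thresholds.otu_identity <= 1):
            raise ConfigError("field 'thresholds.otu_identity' must be in (0, 1]")
        self.long_reads.profile  # validates error rates

    def derived_seed(self, stage: int) -> int:
        """Per-stage seed, deterministic in the master seed."""
        return (self.seed * 1009 + stage * 9973) % (2**31 - 1)


_SECTIONS = {
    "reference": ReferenceConfig,
    "long_reads": LongReadConfig,
    "control": ControlConfig,
    "short_reads": ShortReadConfig,
    "thresholds": Thresholds,
}


def _build_section(cls: type, data: Any, name: str) -> Any:
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"field '{name}' must be a mapping")
    valid = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown field '{name}.{sorted(unknown)[0]}'")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Build and validate a RunConfig; missing required fields and unknown
    keys raise :class:`ConfigError` naming the field."""
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    for required in ("seed", "output_dir"):
        if required not in data:
            raise ConfigError(f"missing required field '{required}'")
    kwargs: dict[str, Any] = {
        "seed": data["seed"],
        "output_dir": data["output_dir"],
    }
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, data.get(name), name)
    if "primers" in data and data["primers"] is not None:
        p = data["primers"]
        if not isinstance(p, dict):
            raise ConfigError("field 'primers' must be a mapping")
        base = DEFAULT_PRIMER_SET
        kwargs["primers"] = PrimerSet(
            full_length=PrimerPair(
                p.get("full_length_fwd", base.full_length.fwd),
                p.get("full_length_rev", base.full_length.rev),
            ),
            short=PrimerPair(
                p.get("short_fwd", base.short.fwd),
                p.get("short_rev", base.short.rev),
            ),
        )
    for scalar in ("community_alpha", "rarefy_depth", "regions_taxon_pair"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    known = set(_SECTIONS) | {
        "seed", "output_dir", "primers",
        "community_alpha", "rarefy_depth", "regions_taxon_pair",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown field '{sorted(unknown)[0]}'")
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def dump_config(config: RunConfig, path: str) -> None:
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
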