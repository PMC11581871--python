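"""YAML configuration holding the genome, library and mapper parameter sets.

Every run logs the resolved configuration (defaults filled in) so a result is
always reproducible from its log.
"""

from __future__ import annotations

import dataclasses
import logging

import yaml

from .aligner import MapperParams
from .errors import ConfigurationError
from .synthetic_data import GenomePairSpec, LibrarySpec

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    genome: GenomePairSpec
    host_library: LibrarySpec
    parasite_library: LibrarySpec
    mapper: MapperParams
    relaxed_max_mismatch: int = 10
    interaction: str = "synthetic"

    def validate(self) -> None:
        self.genome.validate()
        self.host_library.validate()
        self.parasite_library.validate()
        self.mapper.validate()
        max_read = max(self.host_library.read_length,
                       self.parasite_library.read_length)
        if self.genome.gene_length < 2 * max_read:
            raise ConfigurationError(
                f"gene_length ({self.genome.gene_length}) must be >= twice the "
                f"longest read length ({max_read})")
        if self.relaxed_max_mismatch < self.mapper.max_mismatch:
            raise ConfigurationError(
                "relaxed_max_mismatch must be >= mapper.max_mismatch")


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown keys in {name!r}: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | None = None, overrides: dict | None = None
                ) -> PipelineConfig:
    """Load a config file (or defaults) and log the fully resolved values."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, values in overrides.items():
            raw.setdefault(section, {}).update(values)
    host_lib = dict(raw.get("host_library", {}))
    para_lib = dict(raw.get("parasite_library", {}))
    para_lib.setdefault("read_length", 100)  # parasite default: shorter reads
    cfg = PipelineConfig(
        genome=_build(GenomePairSpec, raw.get("genome", {}), "genome"),
        host_library=_build(LibrarySpec, host_lib, "host_library"),
        parasite_library=_build(LibrarySpec, para_lib, "parasite_library"),
        mapper=_build(MapperParams, raw.get("mapper", {}), "mapper"),
        relaxed_max_mismatch=int(raw.get("relaxed_max_mismatch", 10)),
        interaction=str(raw.get("interaction", "synthetic")),
    )
    cfg.validate()
    logger.info("resolved config: %s", resolved_dict(cfg))
    return cfg


def resolved_dict(cfg: PipelineConfig) -> dict:
    return {
        "genome": dataclasses.asdict(cfg.genome),
        "host_library": dataclasses.asdict(cfg.host_library),
        "parasite_library": dataclasses.asdict(cfg.parasite_library),
        "mapper": dataclasses.asdict(cfg.mapper),
        "relaxed_max_mismatch": cfg.relaxed_max_mismatch,
        "interaction": cfg.interaction,
    }


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(resolved_dict(cfg), fh, sort_keys=False)
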