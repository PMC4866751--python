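"""Pipeline configuration: a YAML-serializable, strictly-validated mapping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    ``input_dir`` is a bundle directory as written by the ``simulate``
    subcommand (FASTA, MGF, kinetics CSVs, EMSA CSV, manifest.json);
    ``reference_fasta`` overrides the synthetic reference frame.  Unknown
    keys in a YAML file are rejected.
    """

    input_dir: str
    output_dir: str
    reference_fasta: str | None = None
    tolerance_da: float = 0.5
    oxidation_delta: float = 15.994915
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)
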