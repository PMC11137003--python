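"""CSV schemas, validation, and run manifests.

All tabular I/O is plain CSV (RFC 4180 as written by pandas). Each
pipeline stage validates its input against a named column schema and
raises :class:`SchemaError` with an actionable message; runs record a
manifest (config hash, package version, input hashes, per-stage status)
so a report can be regenerated and checked against the original.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "validate_schema", "read_table",
           "write_table", "RunManifest"]

SCHEMA_VERSION = "1"

#: Required columns per table kind. Units convention: time in minutes,
#: amounts in nmol, concentrations in nmol/mg or uM, masses in Da.
SCHEMAS: dict[str, list[str]] = {
    "mids": ["sample_id", "group", "tissue", "metabolite", "fragment_id",
             "mass_shift", "value", "value_type"],
    "peak_areas": ["sample_id", "group", "tissue", "assay", "analyte",
                   "area", "is_name", "is_area"],
    "bolus": ["sample_id", "group", "time_min", "enrichment"],
    "enzyme": ["sample_id", "group", "assay", "analyte", "area", "is_name",
               "is_area"],
    "concentrations": ["sample_id", "group", "tissue", "analyte",
                       "concentration", "units"],
    "turnover": ["sample_id", "group", "E0", "k", "Q", "Ra"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def validate_schema(df: pd.DataFrame, kind: str, source: str = "<memory>") -> None:
    if kind not in SCHEMAS:
        raise KeyError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{source}: table of kind {kind!r} is missing column(s) "
            f"{missing}; expected columns {SCHEMAS[kind]}"
        )


def read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_schema(df, kind, source=str(path))
    return df


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    if kind is not None:
        validate_schema(df, kind, source=str(path))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to each stage's outputs."""

    config_hash: str
    software_version: str
    schema_version: str = SCHEMA_VERSION
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    created: str = ""

    @classmethod
    def create(cls, config: dict) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            software_version=__version__,
            created=datetime.now(timezone.utc).isoformat(),
        )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256_file(path)

    def mark(self, stage: str, status: str) -> None:
        self.stages[stage] = status

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, directory) -> "RunManifest":
        data = json.loads((Path(directory) / "manifest.json").read_text())
        return cls(**data)
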