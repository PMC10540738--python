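"""YAML-backed run configuration."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from metstab.io_cli.types import RunConfig


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML key-value file; unknown keys are
    rejected; explicit keyword overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "environments" in data and data["environments"] is not None:
        data["environments"] = tuple(data["environments"])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    out = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    out["environments"] = list(out["environments"])
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
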