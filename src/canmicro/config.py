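"""Run configuration, presets, logging and manifest writing."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import model
from .model import ModelParams

__all__ = ["ConfigError", "RunConfig", "load_config", "write_manifest",
           "get_logger"]

PRESETS = ("table1", "two_population", "two_population_disinhibited")

_TOP_KEYS = ("preset", "params", "seed", "dt", "out_dir", "verbosity")


class ConfigError(ValueError):
    pass


def get_logger() -> logging.Logger:
    return logging.getLogger("canmicro")


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG)
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    get_logger().setLevel(level)


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams.table1)
    preset: str = "table1"
    seed: int = 0
    dt: float = 1e-3
    out_dir: str = "."
    verbosity: int = 0

    def echo(self) -> dict:
        return {
            "preset": self.preset,
            "params": model.params_to_dict(self.params),
            "seed": self.seed,
            "dt": self.dt,
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"preset": self.preset,
                            "params": model.params_to_dict(self.params),
                            "seed": self.seed, "dt": self.dt,
                            "out_dir": self.out_dir,
                            "verbosity": self.verbosity}, fh, sort_keys=False)


def _preset_params(name: str) -> ModelParams:
    if name == "table1":
        return ModelParams.table1()
    if name == "two_population":
        return ModelParams.two_population()
    if name == "two_population_disinhibited":
        return ModelParams.two_population_disinhibited()
    raise ConfigError(f"unknown preset {name!r}; valid: {PRESETS}")


def build_config(doc: dict | None) -> RunConfig:
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    preset = doc.get("preset", "table1")
    params = _preset_params(preset)
    overrides = doc.get("params") or {}
    if not isinstance(overrides, dict):
        raise ConfigError("'params' must be a mapping of symbol names")
    if overrides:
        try:
            params = params.replace(**overrides)
        except (KeyError, ValueError) as err:
            raise ConfigError(f"params: {err}") from err
    dt = float(doc.get("dt", 1e-3))
    if dt <= 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    seed = int(doc.get("seed", 0))
    verbosity = int(doc.get("verbosity", 0))
    out_dir = str(doc.get("out_dir", "."))
    return RunConfig(params=params, preset=preset, seed=seed, dt=dt,
                     out_dir=out_dir, verbosity=verbosity)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults (Table-1 three-population model);
    unknown keys and invariant violations raise :class:`ConfigError`
    naming the offending key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = build_config(doc)
    get_logger().info("effective configuration: %s", json.dumps(cfg.echo()))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: RunConfig,
                   outputs: list[str]) -> Path:
    """Record command, effective config, seed and output checksums."""
    from . import __version__
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "version": __version__,
        "config": config.echo(),
        "outputs": {name: _sha256(out_dir / name) for name in outputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
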