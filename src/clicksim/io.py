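"""Run configuration, fixtures, provenance and logging glue.

A run config is a JSON document selecting an assembly (inline, by file
path, or by shipped fixture name, optionally with dotted-key parameter
overrides), a backend (``ode`` or ``ca``) with its parameters, optional
analysis requests, a seed and an output directory.  The schema ships as
``fixtures/runconfig.schema.json``; the reader validates directly and
reports field-level messages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any, Mapping

from .assembly import Assembly, assembly_from_dict, load_assembly
from .ode import OdeParams

__all__ = [
    "RunConfig",
    "load_run_config",
    "fixture_path",
    "load_fixture_assembly",
    "provenance_record",
    "configure_logging",
    "package_version",
]

log = logging.getLogger("clicksim")

FIXTURE_DIR = Path(__file__).parent / "fixtures"

_ODE_KEYS = {"absolute_tolerance", "relative_tolerance", "t_end", "n_samples",
             "extinction_threshold"}
_CA_KEYS = {"width", "height", "sweeps", "densities", "dt", "max_prob"}
_SCAN_KEYS = {"h_grid", "transition_h", "stable_low_h", "stable_high_h",
              "bistable_h", "lag", "n_inits"}


def package_version() -> str:
    try:
        return metadata.version("clicksim")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def configure_logging(debug: bool = False) -> None:
    """Log to stderr, INFO by default, DEBUG on request."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if debug else logging.INFO)


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture file (e.g. ``fig1_4click.json``)."""
    p = FIXTURE_DIR / name
    if not p.exists():
        raise FileNotFoundError(f"no shipped fixture named {name!r}")
    return p


def load_fixture_assembly(name: str = "fig1_4click") -> Assembly:
    return load_assembly(fixture_path(f"{name}.json" if not name.endswith(".json") else name))


@dataclass
class RunConfig:
    assembly: Assembly
    backend: str = "ode"
    ode: OdeParams = field(default_factory=OdeParams)
    ca: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Path = Path(".")
    source: Path | None = None
    raw: dict = field(default_factory=dict)


class ConfigError(ValueError):
    pass


def _resolve_assembly(spec: Any, base: Path) -> Assembly:
    from .assembly import build_canonical_4click

    if isinstance(spec, str):
        cand = base / spec
        if cand.exists():
            return load_assembly(cand)
        try:
            return load_fixture_assembly(spec)
        except FileNotFoundError:
            raise ConfigError(f"assembly: no file or fixture named {spec!r}")
    if isinstance(spec, Mapping):
        if "fixture" in spec or "overrides" in spec:
            name = spec.get("fixture", "fig1_4click")
            overrides = spec.get("overrides", {})
            if name != "fig1_4click":
                raise ConfigError(
                    "assembly.overrides is only supported for the fig1_4click fixture")
            return build_canonical_4click(overrides or None)
        if "path" in spec:
            return load_assembly(base / str(spec["path"]))
        return assembly_from_dict(spec)
    raise ConfigError("assembly must be a string, an object, or {'fixture': ...}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read, validate and default-fill a run config; echo it to the log."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})")
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be an object")
    known = {"assembly", "backend", "ode", "ca", "scan", "seed", "outdir", "_comment"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "assembly" not in raw:
        raise ConfigError(f"{path}: missing required key 'assembly'")
    backend = raw.get("backend", "ode")
    if backend not in ("ode", "ca"):
        raise ConfigError(f"{path}: backend must be 'ode' or 'ca', got {backend!r}")
    if backend == "ode" and "ca" in raw:
        raise ConfigError(
            f"{path}: backend 'ode' does not accept CA keys {sorted(raw['ca'])}")
    if backend == "ca" and "ca" in raw:
        bad = set(raw["ca"]) - _CA_KEYS
        if bad:
            raise ConfigError(f"{path}: unknown ca keys {sorted(bad)}")
    ode_raw = raw.get("ode", {})
    bad = set(ode_raw) - _ODE_KEYS
    if bad:
        raise ConfigError(f"{path}: unknown ode keys {sorted(bad)}")
    scan_raw = raw.get("scan", {})
    bad = set(scan_raw) - _SCAN_KEYS
    if bad:
        raise ConfigError(f"{path}: unknown scan keys {sorted(bad)}")
    if "seed" not in raw:
        log.info("config %s: no seed given, defaulting to 0", path.name)
    seed = int(raw.get("seed", 0))
    assembly = _resolve_assembly(raw["assembly"], path.parent)
    cfg = RunConfig(
        assembly=assembly,
        backend=backend,
        ode=OdeParams(**ode_raw),
        ca=dict(raw.get("ca", {})),
        scan=dict(scan_raw),
        seed=seed,
        outdir=Path(raw.get("outdir", ".")),
        source=path,
        raw=dict(raw),
    )
    log.info("effective config: backend=%s seed=%d ode=%s ca=%s scan=%s",
             cfg.backend, cfg.seed, cfg.ode, cfg.ca or "-", cfg.scan or "-")
    return cfg


def provenance_record(config_path: str | Path | None, seed: int,
                      extra: Mapping[str, Any] | None = None) -> dict:
    """Machine-readable provenance: config hash, seed, package version."""
    rec: dict[str, Any] = {
        "package": "clicksim",
        "version": package_version(),
        "seed": seed,
    }
    if config_path is not None:
        blob = Path(config_path).read_bytes()
        rec["config"] = str(config_path)
        rec["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if extra:
        rec.update(extra)
    return rec
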