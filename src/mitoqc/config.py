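"""Flat key/value configuration files and run manifests.

A configuration file (YAML or JSON; YAML is a superset) holds a flat mapping
whose keys are quality-control parameter fields plus a small set of run
settings.  Unknown keys are rejected; missing parameter keys fall back to
the nominal preset.  ``tau`` (mixing time constant, days) may be given
instead of ``ff_scale`` and is resolved through the calibration anchor
τ(ff_scale=1) = 7.5 days.

Every CLI run writes a ``manifest.json`` capturing the configuration
snapshot, package version, master seed and child-seed derivation rule, wall
times and output inventory, so any output can be regenerated bit-identically
by re-running with the recorded settings (single-threaded).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calibration import scale_for_tau
from .kinetics import QCParams

__all__ = ["RunConfig", "RunManifest", "load_config", "write_config"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(QCParams)}
#: Run-setting keys accepted alongside parameter keys.
_SETTING_KEYS = {
    "tau",
    "t_end",
    "n_cells",
    "seed",
    "preset",
    "threshold",
    "n_samples",
    "n_cells_per_point",
    "record_dt",
}


@dataclass
class RunConfig:
    """Validated configuration: parameters plus run settings."""

    params: QCParams
    settings: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load and validate a flat configuration file.

    Raises ``ValueError`` listing every violation (unknown keys, type or
    range errors) at once.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a flat key/value mapping")
    errors = []
    unknown = set(doc) - _PARAM_KEYS - _SETTING_KEYS
    for k in sorted(unknown):
        errors.append(f"unknown key: {k}")
    if "tau" in doc and "ff_scale" in doc:
        errors.append("give either tau or ff_scale, not both")
    param_kwargs = {}
    for k in _PARAM_KEYS & set(doc):
        v = doc[k]
        if k == "retrograde_uses_cell_fraction":
            if not isinstance(v, bool):
                errors.append(f"{k} must be a boolean")
                continue
        elif not isinstance(v, (int, float)) or isinstance(v, bool):
            errors.append(f"{k} must be a number")
            continue
        param_kwargs[k] = v
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    try:
        params = QCParams.nominal().with_(**param_kwargs)
        if "tau" in doc:
            params = scale_for_tau(float(doc["tau"]), params)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    settings = {k: doc[k] for k in _SETTING_KEYS & set(doc)}
    return RunConfig(params=params, settings=settings)


def write_config(params: QCParams, path, settings: dict | None = None) -> None:
    """Serialize parameters (and optional run settings) to a YAML file."""
    doc = dict(params.to_dict())
    doc.update(settings or {})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    options: dict
    params: dict
    master_seed: int
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    child_seed_rule: str = (
        "numpy SeedSequence([master_seed, *counters]) -> first uint32 & 0x7fffffff"
    )
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path
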