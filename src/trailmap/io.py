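"""Configuration files, event-log serialisation, manifests, trail snapshots.

All artefacts are plain text and diff-able:

* **Config** — a flat YAML mapping of documented keys onto
  :class:`~trailmap.simulation.SimulationConfig` and its routing
  parameters.  Unknown keys are rejected; missing keys take the documented
  defaults; the evaporation rate is always derived from the half-life.
* **Event log** — JSONL (one record per line) or CSV with the fixed column
  schema; both round-trip to identical in-memory logs, with timestamps at
  full float precision.
* **Run manifest** — JSON recording the fully resolved configuration, the
  seed, the package version, and a checksum inventory of the output files;
  :func:`replay_manifest` regenerates a run byte-identically from it.
* **Trail snapshot** — CSV of (helper_id, tau, last_evaporation_hour) that
  round-trips losslessly, plus a JSONL audit log of moderator operations.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import yaml

from trailmap.pheromone import RoutingParams, TrailTable
from trailmap.simulation import EventLog, SimulationConfig

__all__ = [
    "ConfigError",
    "CONFIG_SCHEMA_VERSION",
    "load_config",
    "save_config",
    "config_to_dict",
    "write_event_log",
    "read_event_log",
    "write_metrics_json",
    "write_manifest",
    "replay_manifest",
    "trail_table_to_csv",
    "trail_table_from_csv",
    "write_audit_log",
]

CONFIG_SCHEMA_VERSION = 1

_SIM_KEYS = {
    f.name for f in dc_fields(SimulationConfig) if f.name != "routing"
}
_ROUTING_KEYS = {f.name for f in dc_fields(RoutingParams)}
_META_KEYS = {"schema_version"}

_FLOAT_FMT = "%.17g"  # round-trips any IEEE double exactly


class ConfigError(ValueError):
    """A configuration file failed validation."""


def config_to_dict(config: SimulationConfig) -> Dict:
    """Flat key-value form of a configuration (manifest- and YAML-ready)."""
    out = {"schema_version": CONFIG_SCHEMA_VERSION}
    for name in sorted(_SIM_KEYS):
        out[name] = getattr(config, name)
    for name in sorted(_ROUTING_KEYS):
        out[name] = getattr(config.routing, name)
    out["evaporation_rate"] = config.routing.evaporation_rate  # derived, echoed
    return out


def _config_from_dict(data: Dict) -> SimulationConfig:
    known = _SIM_KEYS | _ROUTING_KEYS | _META_KEYS | {"evaporation_rate"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    data = dict(data)
    data.pop("schema_version", None)
    data.pop("evaporation_rate", None)  # always re-derived from the half-life
    routing_kwargs = {k: data.pop(k) for k in list(data) if k in _ROUTING_KEYS}
    try:
        routing = RoutingParams(**routing_kwargs)
        cfg = SimulationConfig(routing=routing, **data)
        cfg.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a simulation configuration from a flat YAML file.

    An empty file yields the full default configuration.  Unknown keys,
    type mismatches, and constraint violations raise :class:`ConfigError`
    with a named message.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    return _config_from_dict(data)


def save_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    """Write a configuration as flat YAML (every parameter explicit)."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True)
    )


# -- event logs -----------------------------------------------------------


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer event-log format from {path.name!r}")


def write_event_log(
    log: EventLog, path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Serialise an event log to JSONL or CSV (inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "jsonl":
            with path.open("w", newline="\n") as fh:
                for rec in log:
                    fh.write(json.dumps(rec, sort_keys=True))
                    fh.write("\n")
        elif fmt == "csv":
            with path.open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(EventLog.FIELDS)
                for rec in log:
                    writer.writerow(
                        [
                            _csv_cell(rec[name], name)
                            for name in EventLog.FIELDS
                        ]
                    )
        else:
            raise ValueError(f"unknown event-log format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write event log to {path}: {exc}") from exc


def _csv_cell(value, name: str) -> str:
    if value is None:
        return ""
    if name in ("t_min", "tau_after"):
        return _FLOAT_FMT % value
    return str(value)


_INT_FIELDS = ("request_id", "seeker_id", "helper_id", "rating")
_FLOAT_FIELDS = ("t_min", "tau_after")


def read_event_log(path: Union[str, Path], fmt: Optional[str] = None) -> EventLog:
    """Read a JSONL or CSV event log back into memory."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = []
    try:
        if fmt == "jsonl":
            with path.open() as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        records.append(json.loads(line))
        elif fmt == "csv":
            with path.open(newline="") as fh:
                reader = csv.DictReader(fh)
                for row in reader:
                    rec: dict = {"event": row["event"]}
                    for name in _FLOAT_FIELDS:
                        rec[name] = float(row[name]) if row[name] != "" else None
                    for name in _INT_FIELDS:
                        rec[name] = int(row[name]) if row[name] != "" else None
                    records.append(rec)
        else:
            raise ValueError(f"unknown event-log format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot read event log from {path}: {exc}") from exc
    return EventLog(records=records)


def write_metrics_json(metrics, path: Union[str, Path]) -> None:
    """Write a MetricsResult as JSON."""
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2) + "\n")


def write_lorenz_csv(lorenz_points, path: Union[str, Path]) -> None:
    """Write Lorenz curve points as a two-column CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cumulative_helper_fraction", "cumulative_load_fraction"])
        for x, y in lorenz_points:
            writer.writerow([_FLOAT_FMT % x, _FLOAT_FMT % y])


# -- manifests ------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    config: SimulationConfig,
    out_dir: Union[str, Path],
    outputs: Sequence[Union[str, Path]],
    path_name: str = "manifest.json",
) -> Path:
    """Record the resolved config, seed, version, and output checksums."""
    from trailmap import __version__

    out_dir = Path(out_dir)
    manifest = {
        "artifact_version": __version__,
        "config": config_to_dict(config),
        "seed": config.seed,
        "outputs": {
            Path(p).name: _sha256(Path(p)) for p in outputs
        },
    }
    path = out_dir / path_name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def replay_manifest(manifest_path: Union[str, Path], out_dir: Union[str, Path]):
    """Re-run a simulation from its manifest; returns (log, metrics, files).

    The regenerated event log and metrics are written into ``out_dir`` with
    the names recorded in the manifest; callers can compare checksums to
    verify byte-identical reproduction.
    """
    from trailmap.simulation import run_simulation

    manifest = json.loads(Path(manifest_path).read_text())
    config = _config_from_dict(manifest["config"])
    log, metrics = run_simulation(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in manifest["outputs"]:
        target = out_dir / name
        if name.endswith((".jsonl", ".csv")) and "lorenz" not in name:
            write_event_log(log, target)
        elif name.endswith(".json"):
            write_metrics_json(metrics, target)
        else:  # pragma: no cover - unknown artefacts are skipped
            continue
        written.append(target)
    return log, metrics, written


# -- trail snapshots ------------------------------------------------------


def trail_table_to_csv(table: TrailTable, path: Union[str, Path]) -> None:
    """Snapshot a trail table as CSV; round-trips at full float precision."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["helper_id", "tau", "last_evaporation_hour"])
        for hid in table.helper_ids:
            writer.writerow(
                [hid, _FLOAT_FMT % table.tau(hid), table.last_evaporation_hour]
            )


def trail_table_from_csv(path: Union[str, Path]) -> TrailTable:
    """Restore a trail table from a CSV snapshot.

    Helper ids are read back as integers when possible, else as strings.
    """
    table = TrailTable()
    last_hour = 0
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            hid: Union[int, str]
            try:
                hid = int(row["helper_id"])
            except ValueError:
                hid = row["helper_id"]
            table.register(hid)
            table._set(hid, float(row["tau"]))
            last_hour = int(row["last_evaporation_hour"])
    table.last_evaporation_hour = last_hour
    return table


def write_audit_log(table: TrailTable, path: Union[str, Path]) -> None:
    """Write a trail table's moderator audit records as JSONL."""
    with Path(path).open("w", newline="\n") as fh:
        for rec in table.audit:
            fh.write(json.dumps(rec, sort_keys=True))
            fh.write("\n")
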