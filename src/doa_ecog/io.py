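"""Readers/writers for recordings, configs, and run outputs.

A recording is stored as a CSV trace (``t_s, ch_contra, ch_ipsi`` in
input-referred microvolts, optionally a ``depth`` column for synthetic ground
truth) plus a JSON sidecar (same stem, ``.json``) carrying the sample rate,
protocol, stimulus onsets, and units. Configs serialize to YAML; run outputs
are TSV/JSON files listed in a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import AnesthesiaProtocol, GeneratorConfig, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "sidecar_path",
    "save_config",
    "load_generator_config",
    "write_outputs",
    "verify_manifest",
]


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def save_recording(rec: Recording, path: Path | str, include_depth: bool = True) -> Path:
    """Write the trace CSV and its JSON sidecar; returns the CSV path."""
    path = Path(path)
    cols = {
        "t_s": rec.times(),
        "ch_contra": rec.channel_contra,
        "ch_ipsi": rec.channel_ipsi,
    }
    if include_depth and rec.ground_truth_depth is not None:
        cols["depth"] = rec.ground_truth_depth
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    meta = {
        "animal_id": rec.animal_id,
        "sample_rate_hz": rec.sample_rate,
        "units": "uV",
        "input_referred": rec.input_referred,
        "protocol_segments": [[c, d] for c, d in rec.protocol.segments],
        "stim_onsets_s": rec.stim_onsets.tolist(),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path: Path | str, format: str = "csv") -> Recording:
    """Load a recording and validate channels, units, and sidecar metadata."""
    if format != "csv":
        raise ValueError(f"unsupported recording format: {format!r} (csv only)")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = sidecar_path(path)
    if not side.exists():
        raise ValueError(f"missing sidecar JSON: {side}")
    meta = json.loads(side.read_text())
    if meta.get("units") != "uV":
        raise ValueError(f"expected input-referred uV data, sidecar says {meta.get('units')!r}")
    if not meta.get("input_referred", False):
        raise ValueError("recording not flagged input-referred (amplifier gain present?)")
    frame = pd.read_csv(path)
    missing = {"ch_contra", "ch_ipsi"} - set(frame.columns)
    if missing:
        raise ValueError(
            f"missing channel columns {sorted(missing)}; found {list(frame.columns)}"
        )
    return Recording(
        channel_contra=frame["ch_contra"].to_numpy(),
        channel_ipsi=frame["ch_ipsi"].to_numpy(),
        sample_rate=float(meta["sample_rate_hz"]),
        stim_onsets=np.asarray(meta["stim_onsets_s"], dtype=float),
        protocol=AnesthesiaProtocol(
            tuple((float(c), float(d)) for c, d in meta["protocol_segments"])
        ),
        animal_id=str(meta["animal_id"]),
        ground_truth_depth=frame["depth"].to_numpy() if "depth" in frame else None,
    )


def save_config(cfg, path: Path | str) -> Path:
    """Serialize any of the package's config dataclasses to YAML."""
    path = Path(path)
    data = dataclasses.asdict(cfg)
    data["_config_type"] = type(cfg).__name__
    path.write_text(yaml.safe_dump(_jsonable(data), sort_keys=True))
    return path


def load_generator_config(path: Path | str) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    data.pop("_config_type", None)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
    for key in ("osc_band_hz", "slow_band_hz"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return GeneratorConfig(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(artifacts: dict[str, object], out_dir: Path | str) -> Path:
    """Write named artifacts (DataFrame -> TSV, dict/list -> JSON, str -> text)
    into ``out_dir`` and a ``manifest.json`` with a sha256 per file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in artifacts.items():
        path = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False, float_format="%.9g")
        elif isinstance(obj, (dict, list)):
            path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
        elif isinstance(obj, str):
            path.write_text(obj)
        else:
            raise TypeError(f"cannot serialize artifact {name!r} of type {type(obj)}")
        files.append(path)
    manifest = {p.name: _sha256(p) for p in files}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir / "manifest.json"


def verify_manifest(manifest_path: Path | str) -> dict[str, bool]:
    """Recompute checksums for every manifest entry; True means intact."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    return {
        name: (manifest_path.parent / name).exists()
        and _sha256(manifest_path.parent / name) == digest
        for name, digest in manifest.items()
    }
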