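"""Readers and writers for the package's plain-text formats.

Formats:
  * qPCR plate — long CSV: condition, site_label, timepoint_min, replicate,
    quantity.
  * lane profile set — TSV matrix (``position`` column, ``ladder`` column,
    one column per lane named ``t<min>``) plus a JSON sidecar carrying
    timepoints, ladder band sizes, encoding, seed and generative truth.
  * run manifest — JSON listing of output files with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .simulate import LaneProfileSet

PLATE_COLUMNS = ["condition", "site_label", "timepoint_min", "replicate", "quantity"]


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False, float_format="%.10g")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"plate CSV not found: {path}")
    plate = pd.read_csv(path, dtype={"site_label": str})
    missing = set(PLATE_COLUMNS) - {"condition"} - set(plate.columns)
    if missing:
        raise ValidationError(f"plate CSV {path} missing columns {sorted(missing)}")
    return plate


def write_lane_set(lane_set: LaneProfileSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (profiles) and ``<prefix>.json`` (sidecar)."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    data = {"position": lane_set.positions, "ladder": lane_set.ladder}
    for t, lane in lane_set.lanes:
        data[f"t{t:g}"] = lane
    pd.DataFrame(data).to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    meta = {
        "encoding": lane_set.encoding,
        "timepoints_min": [t for t, _ in lane_set.lanes],
        "ladder_bands_bp": list(lane_set.ladder_bands),
        "flags": lane_set.flags,
        **lane_set.meta,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv, sidecar


def read_lane_set(tsv: str | Path, sidecar: str | Path | None = None) -> LaneProfileSet:
    tsv = Path(tsv)
    if not tsv.exists():
        raise ValidationError(f"lane TSV not found: {tsv}")
    sidecar = Path(sidecar) if sidecar else tsv.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"lane sidecar JSON not found: {sidecar}")
    table = pd.read_csv(tsv, sep="\t")
    for col in ("position", "ladder"):
        if col not in table.columns:
            raise ValidationError(f"lane TSV {tsv} missing column {col!r}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    timepoints = meta.get("timepoints_min")
    if timepoints is None:
        raise ValidationError(f"sidecar {sidecar} missing 'timepoints_min'")
    lanes = []
    for t in timepoints:
        col = f"t{t:g}"
        if col not in table.columns:
            raise ValidationError(f"lane TSV {tsv} missing lane column {col!r}")
        lanes.append((float(t), table[col].to_numpy(dtype=float)))
    return LaneProfileSet(
        positions=table["position"].to_numpy(dtype=float),
        ladder=table["ladder"].to_numpy(dtype=float),
        ladder_bands=tuple(meta.get("ladder_bands_bp", ())),
        ladder_band_positions=tuple(meta.get("ladder_band_positions", ())),
        lanes=lanes,
        encoding=meta.get("encoding", "linear"),
        flags=list(meta.get("flags", [])),
        meta={k: v for k, v in meta.items() if k not in
              ("encoding", "timepoints_min", "ladder_bands_bp", "flags")},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, files: list[Path], seed: int | None = None) -> Path:
    """Write ``manifest.json`` listing files with checksums, version, seed."""
    out_dir = Path(out_dir)
    entries = [
        {"file": str(p.relative_to(out_dir)), "sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in sorted(files)
    ]
    payload = {"package_version": __version__, "seed": seed, "files": entries}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def verify_manifest(path: str | Path) -> list[str]:
    """Return a list of mismatched files (empty when all checksums agree)."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    bad = []
    for entry in payload["files"]:
        target = path.parent / entry["file"]
        if not target.exists() or _sha256(target) != entry["sha256"]:
            bad.append(entry["file"])
    return bad
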