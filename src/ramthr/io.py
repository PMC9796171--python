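"""Delimited-text input/output and schema validation.

Profiles travel as tab-separated text with columns ``root_id``,
``cell_index`` (contiguous from 1 per root) and ``length_um``; all other
outputs are TSV tables or schema-versioned JSON reports.  Every CLI run
writes a manifest (package version, config hash, seed) next to its
outputs so reruns can be verified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .msc import CellLengthProfile
from .thr_model import AminoAcidProfile

PROFILE_COLUMNS = ("root_id", "cell_index", "length_um")
REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    errors: tuple[str, ...]

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise ValueError("invalid profiles file:\n" + "\n".join(self.errors))


def validate_profiles_frame(frame: pd.DataFrame) -> ValidationReport:
    """Schema check with line-numbered diagnostics (line 1 = header)."""
    errors: list[str] = []
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        return ValidationReport(False, (f"missing column(s): {missing}",))
    for col in ("cell_index", "length_um"):
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        errors.extend(f"line {i + 2}: non-numeric {col}={frame.loc[i, col]!r}"
                      for i in bad)
    if errors:
        return ValidationReport(False, tuple(errors))
    lengths = frame["length_um"].astype(float)
    errors.extend(
        f"line {i + 2}: non-positive length_um={lengths[i]} (root {frame.loc[i, 'root_id']})"
        for i in frame.index[lengths <= 0])
    for root_id, group in frame.groupby("root_id", sort=False):
        idx = group["cell_index"].astype(int).to_numpy()
        if not np.array_equal(idx, np.arange(1, idx.size + 1)):
            errors.append(
                f"root {root_id!r}: cell_index must be contiguous from 1, got "
                f"{idx[:5].tolist()}{'...' if idx.size > 5 else ''}")
    return ValidationReport(not errors, tuple(errors))


def read_profiles(path: str | Path) -> list[CellLengthProfile]:
    """Read and validate a profiles TSV into ordered profiles."""
    frame = pd.read_csv(path, sep="\t")
    validate_profiles_frame(frame).raise_if_failed()
    return [
        CellLengthProfile(str(root_id), group["length_um"].astype(float).to_numpy())
        for root_id, group in frame.groupby("root_id", sort=False)
    ]


def write_profiles(profiles: list[CellLengthProfile], path: str | Path) -> None:
    rows = [
        {"root_id": p.root_id, "cell_index": i + 1, "length_um": length}
        for p in profiles for i, length in enumerate(p.lengths)
    ]
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_amino_acid_profile(profile: AminoAcidProfile, path: str | Path) -> None:
    data = {"position": profile.positions, "thr": profile.thr}
    if profile.model_variant == "extended":
        data["gly"] = profile.gly
        data["ile"] = profile.ile
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_json_report(payload: dict, path: str | Path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write the run manifest; identical manifests imply identical
    numeric outputs (all computations are seeded and deterministic)."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=_jsonable)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "seed": seed,
    }
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")
    return path
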