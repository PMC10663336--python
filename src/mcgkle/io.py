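"""Cohort manifests, array containers, pipeline configuration and atomic writes.

File conventions: recordings are HDF5 (channels x samples plus R peaks and
metadata); averaged maps and feature tables are plain CSV for diff-ability;
every boundary expresses segment cursors in milliseconds relative to the R
peak — samples are an internal convention only.  All writes go through a
write-temp-then-rename contract so interrupted runs never leave truncated
artefacts, and every artefact carries the configuration fingerprint it was
produced under.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .preprocess import AveragedMap, cursors_ms_to_samples, cursors_samples_to_ms
from .synth import CmfmRecording, CohortSpec

__all__ = [
    "PipelineConfig",
    "atomic_write_bytes",
    "atomic_write_text",
    "write_recording",
    "read_recording",
    "write_manifest",
    "read_manifest",
    "validate_manifest",
    "write_averaged_map",
    "read_averaged_map",
    "write_feature_table",
]

_CURSOR_KEYS = ("qrs_onset", "qrs_end", "stt_onset", "stt_end")
_GROUPS = ("healthy", "pathology")


class PipelineConfig(BaseModel):
    """Every tunable of the pipeline; defaults are the published configuration."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSpec = Field(default_factory=CohortSpec)
    mode: str = Field("resampled", pattern="^(fixed|resampled)$")
    qrs_fixed_n: int = 80
    stt_fixed_n: int = 250
    qrs_resampled_n: int = 20
    stt_resampled_n: int = 40
    interpolation: str = Field("linear", pattern="^(linear|cubic)$")
    distribution_strategy: str = Field("abs", pattern="^(abs|square|minshift)$")
    eps_rel: float = Field(1e-6, gt=0)
    lda_ridge: float = Field(1e-3, ge=0)
    baseline_correction: bool = True
    baseline_window: int = Field(100, gt=0)
    correlation_warn_threshold: float = Field(0.2, gt=0)
    reference_group: str = Field("healthy", pattern="^(healthy|pathology)$")

    def n_out(self, name: str) -> int:
        key = f"{name.lower()}_{self.mode}_n"
        return int(getattr(self, key))

    def fingerprint(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        atomic_write_text(path, yaml.safe_dump(self.model_dump(), sort_keys=True))


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


class FingerprintMismatch(RuntimeError):
    pass


def _check_fingerprint(found: str | None, expected: str | None, what: str) -> None:
    if expected is not None and found is not None and found != expected:
        raise FingerprintMismatch(
            f"{what}: config fingerprint {found!r} does not match expected "
            f"{expected!r}")


# -- recordings -------------------------------------------------------------

def write_recording(path, rec: CmfmRecording, fingerprint: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            f.create_dataset("r_peaks", data=rec.r_peaks)
            f.attrs["subject_id"] = rec.subject_id
            f.attrs["group"] = rec.group
            f.attrs["fs_hz"] = rec.fs_hz
            for k in _CURSOR_KEYS:
                f.attrs[f"cursor_{k}_ms"] = float(rec.true_cursors_ms[k])
            if fingerprint:
                f.attrs["config_fingerprint"] = fingerprint
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_recording(path, expected_fingerprint: str | None = None) -> CmfmRecording:
    with h5py.File(path, "r") as f:
        _check_fingerprint(f.attrs.get("config_fingerprint"),
                           expected_fingerprint, str(path))
        return CmfmRecording(
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
            signal=f["signal"][...],
            fs_hz=float(f.attrs["fs_hz"]),
            r_peaks=f["r_peaks"][...],
            true_cursors_ms={k: float(f.attrs[f"cursor_{k}_ms"])
                             for k in _CURSOR_KEYS},
        )


# -- manifest ---------------------------------------------------------------

def write_manifest(path, rows: list[dict]) -> None:
    """Cohort manifest CSV: one row per subject with group, file and cursors."""
    cols = ["subject_id", "group", "recording_path", "fs_hz", "system_tag",
            *[f"{k}_ms" for k in _CURSOR_KEYS]]
    df = pd.DataFrame(rows, columns=cols)
    atomic_write_text(path, df.to_csv(index=False))


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def validate_manifest(path) -> list[str]:
    """All invariant violations in the manifest; empty list iff valid."""
    path = Path(path)
    try:
        df = read_manifest(path)
    except Exception as exc:
        raise ValueError(f"unreadable manifest {path}: {exc}") from exc
    violations: list[str] = []
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    for d in dupes:
        violations.append(f"duplicate subject_id: {d}")
    for idx, row in df.iterrows():
        if row["group"] not in _GROUPS:
            violations.append(f"row {idx}: unknown group {row['group']!r}")
        rec_path = path.parent / str(row["recording_path"])
        if not rec_path.exists():
            violations.append(f"row {idx}: missing recording file {rec_path}")
        for k in _CURSOR_KEYS:
            col = f"{k}_ms"
            if col not in row or pd.isna(row[col]):
                violations.append(f"row {idx}: missing cursor {col}")
        if not (row.get("fs_hz", 0) > 0):
            violations.append(f"row {idx}: non-positive fs_hz")
    return violations


# -- averaged maps ----------------------------------------------------------

def write_averaged_map(dir_path, amap: AveragedMap,
                       fingerprint: str | None = None) -> Path:
    """36-column x n_samples-row CSV (column = grid position, row = sample)
    plus a JSON metadata sidecar; round-trips bit-exactly (%.17g)."""
    dir_path = Path(dir_path)
    csv_path = dir_path / f"{amap.subject_id}_map.csv"
    header = ",".join(f"pos{i:02d}" for i in range(amap.n_positions))
    body = "\n".join(",".join(f"{v:.17g}" for v in row) for row in amap.B.T)
    atomic_write_text(csv_path, header + "\n" + body + "\n")
    meta = {
        "subject_id": amap.subject_id,
        "group": amap.group,
        "fs_hz": amap.fs_hz,
        "r_index": amap.r_index,
        "cursors_ms": cursors_samples_to_ms(amap.cursors, amap.r_index),
        "gamma": amap.gamma,
        "normalized": amap.normalized,
        "config_fingerprint": fingerprint,
    }
    atomic_write_text(csv_path.with_suffix(".json"),
                      json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def read_averaged_map(csv_path, expected_fingerprint: str | None = None
                      ) -> AveragedMap:
    csv_path = Path(csv_path)
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    _check_fingerprint(meta.get("config_fingerprint"), expected_fingerprint,
                       str(csv_path))
    B = np.loadtxt(csv_path, delimiter=",", skiprows=1).T
    return AveragedMap(
        subject_id=meta["subject_id"],
        B=B,
        cursors=cursors_ms_to_samples(meta["cursors_ms"], meta["r_index"]),
        fs_hz=meta["fs_hz"],
        r_index=meta["r_index"],
        gamma=meta["gamma"],
        normalized=meta["normalized"],
        group=meta.get("group"),
    )


# -- feature tables ---------------------------------------------------------

def write_feature_table(path, rows: list[dict]) -> None:
    """Cohort KLE feature table CSV.

    One row per subject and segment: subject_id, group, segment, mode,
    native_length_ms, then f_1..f_n in %.17g so reruns are byte-identical.
    """
    if not rows:
        raise ValueError("no feature rows to write")
    n_feat = len(rows[0]["values"])
    header = ["subject_id", "group", "segment", "mode", "native_length_ms",
              *[f"f_{i + 1}" for i in range(n_feat)]]
    lines = [",".join(header)]
    for r in rows:
        vals = ",".join(f"{v:.17g}" for v in r["values"])
        lines.append(f"{r['subject_id']},{r['group']},{r['segment']},"
                     f"{r['mode']},{r['native_length_ms']:.17g},{vals}")
    atomic_write_text(path, "\n".join(lines) + "\n")
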