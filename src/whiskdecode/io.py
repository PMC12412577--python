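"""Dataset and model round-tripping plus run manifests.

Cohorts are stored as one HDF5 group per subject with datasets ``neural``,
``trajectory`` and optionally ``emg``, each carrying ``fs_hz`` and ``unit``
attributes; the group carries ``latency_ms`` when known. A flat-CSV layout
(one ``time_s,value`` file per channel) is provided for interoperability.
"""

from __future__ import annotations

import json
import subprocess
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd

from .recording import DataError, Recording, SubjectDataset

__all__ = [
    "save_cohort",
    "load_dataset",
    "save_subject_csv",
    "load_subject_csv",
    "RunManifest",
]

_CHANNELS = ("neural", "trajectory", "emg")


def save_cohort(cohort: List[SubjectDataset], path) -> None:
    """Write a cohort to one HDF5 container (one group per subject)."""
    with h5py.File(path, "w") as f:
        for ds in cohort:
            g = f.create_group(ds.subject_id)
            for name in _CHANNELS:
                rec: Optional[Recording] = getattr(ds, name)
                if rec is None:
                    continue
                d = g.create_dataset(name, data=rec.samples)
                d.attrs["fs_hz"] = rec.fs_hz
                d.attrs["unit"] = rec.unit
            if ds.ground_truth_latency_ms is not None:
                g.attrs["latency_ms"] = ds.ground_truth_latency_ms


def _rec_from_h5(dset, kind: str) -> Recording:
    if "fs_hz" not in dset.attrs:
        raise DataError(f"dataset {dset.name!r} is missing the fs_hz attribute")
    samples = np.asarray(dset[()])
    if not np.isfinite(samples).all():
        raise DataError(f"dataset {dset.name!r} contains NaN/inf samples")
    return Recording(samples, float(dset.attrs["fs_hz"]), str(dset.attrs.get("unit", "uV")), kind)


def load_dataset(path, subject_id: Optional[str] = None):
    """Load one subject (``subject_id`` given) or the whole cohort (list)."""
    with h5py.File(path, "r") as f:
        ids = [subject_id] if subject_id is not None else sorted(f.keys())
        out = []
        for sid in ids:
            if sid not in f:
                raise DataError(f"subject {sid!r} not found in {path}")
            g = f[sid]
            if "neural" not in g or "trajectory" not in g:
                raise DataError(f"subject {sid!r} is missing a required channel")
            ds = SubjectDataset(
                subject_id=sid,
                neural=_rec_from_h5(g["neural"], "neural"),
                trajectory=_rec_from_h5(g["trajectory"], "trajectory"),
                emg=_rec_from_h5(g["emg"], "emg") if "emg" in g else None,
                ground_truth_latency_ms=float(g.attrs["latency_ms"]) if "latency_ms" in g.attrs else None,
            )
            out.append(ds)
    return out[0] if subject_id is not None else out


def save_subject_csv(ds: SubjectDataset, directory) -> None:
    """One ``time_s,value`` CSV per channel plus a small JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"subject_id": ds.subject_id, "channels": {}}
    if ds.ground_truth_latency_ms is not None:
        meta["latency_ms"] = ds.ground_truth_latency_ms
    for name in _CHANNELS:
        rec: Optional[Recording] = getattr(ds, name)
        if rec is None:
            continue
        pd.DataFrame({"time_s": rec.times_s, "value": rec.samples}).to_csv(
            directory / f"{name}.csv", index=False
        )
        meta["channels"][name] = {"fs_hz": rec.fs_hz, "unit": rec.unit}
    (directory / "subject.json").write_text(json.dumps(meta, indent=2))


def load_subject_csv(directory) -> SubjectDataset:
    directory = Path(directory)
    meta = json.loads((directory / "subject.json").read_text())
    recs = {}
    for name, info in meta["channels"].items():
        df = pd.read_csv(directory / f"{name}.csv")
        recs[name] = Recording(df["value"].to_numpy(), info["fs_hz"], info["unit"], name)
    return SubjectDataset(
        subject_id=meta["subject_id"],
        neural=recs["neural"],
        trajectory=recs["trajectory"],
        emg=recs.get("emg"),
        ground_truth_latency_ms=meta.get("latency_ms"),
    )


def _code_version() -> str:
    try:
        return (
            subprocess.run(
                ["git", "rev-parse", "--short", "HEAD"],
                capture_output=True,
                text=True,
                cwd=Path(__file__).parent,
                timeout=5,
            ).stdout.strip()
            or "unknown"
        )
    except Exception:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record written next to every artifact-producing command."""

    command: str
    config: Dict = field(default_factory=dict)
    seeds: List[int] = field(default_factory=list)
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    code_version: str = field(default_factory=_code_version)
    timestamp: float = field(default_factory=time.time)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
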