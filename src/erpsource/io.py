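"""Delimited-text interchange formats for ERP sets, maps and tables.

An ErpSet on disk is one tab-separated ``channels x time`` matrix per
subject x condition (header row of latencies in ms, first column the channel
name) plus a ``manifest.tsv`` listing subject, task, match and filename, and
a small JSON sidecar with the sampling metadata.  Statistical and source maps
use the long formats documented on their classes.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ErpSet
from .headmodel import LeadField, SourceSpace

__all__ = ["write_erpset", "read_erpset", "write_leadfield", "read_leadfield",
           "write_ismaps", "read_ismaps", "file_sha256"]


class SchemaError(ValueError):
    """Malformed or inconsistent interchange files."""


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_erpset(erps: ErpSet, directory) -> Path:
    """Write one matrix file per subject x condition plus manifest + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = erps.times_ms
    rows = []
    for s in range(erps.n_subjects):
        for c, cond in enumerate(erps.conditions):
            task, match = cond.split("_")
            fname = f"sub{s:02d}_{task}_{match}.tsv"
            df = pd.DataFrame(erps.data[s, c], index=list(erps.channel_names),
                              columns=[f"{v:.3f}" for v in t])
            df.to_csv(directory / fname, sep="\t", index_label="channel",
                      float_format="%.17g")
            rows.append({"subject": s, "task": task, "match": match,
                         "filename": fname})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
    meta = {"fs": erps.fs, "baseline_ms": erps.baseline_ms,
            "channels": list(erps.channel_names),
            "conditions": list(erps.conditions)}
    (directory / "erpset.json").write_text(json.dumps(meta, indent=1))
    return directory / "manifest.tsv"


def read_erpset(directory) -> ErpSet:
    """Read an ErpSet written by :func:`write_erpset` (full-precision round trip)."""
    directory = Path(directory)
    meta_path = directory / "erpset.json"
    if not meta_path.exists():
        raise SchemaError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    channels = tuple(meta["channels"])
    conditions = tuple(meta["conditions"])
    subjects = sorted(manifest["subject"].unique())
    data = None
    ref_times = None
    for _, row in manifest.iterrows():
        cond = f"{row['task']}_{row['match']}"
        if cond not in conditions:
            raise SchemaError(f"unknown condition label {cond!r} in manifest")
        path = directory / row["filename"]
        if not path.exists():
            raise SchemaError(f"manifest references missing file {row['filename']}")
        df = pd.read_csv(path, sep="\t", index_col="channel",
                         float_precision="round_trip")
        if tuple(df.index) != channels:
            missing = set(channels) - set(df.index)
            extra = set(df.index) - set(channels)
            raise SchemaError(
                f"{row['filename']}: channel set mismatch "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})")
        times = df.columns.to_numpy(float)
        if ref_times is None:
            ref_times = times
            data = np.empty((len(subjects), len(conditions), len(channels),
                             len(times)))
        elif not np.array_equal(times, ref_times):
            raise SchemaError(f"{row['filename']}: inconsistent latency grid")
        s = subjects.index(row["subject"])
        data[s, conditions.index(cond)] = df.to_numpy(float)
    return ErpSet(data=data, fs=float(meta["fs"]),
                  baseline_ms=float(meta["baseline_ms"]),
                  channel_names=channels, conditions=conditions)


def write_leadfield(lf: LeadField, path) -> None:
    """Binary array container plus a sidecar text header."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), lf.matrix)
    header = (f"channels: {len(lf.channel_names)}\n"
              f"generators: {lf.n_generators}\n"
              f"units: {lf.units}\n"
              f"reference_applied: {lf.reference_applied}\n"
              f"channel_names: {' '.join(lf.channel_names)}\n")
    path.with_suffix(".hdr").write_text(header)


def read_leadfield(path) -> LeadField:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npy"))
    hdr = dict(line.split(": ", 1)
               for line in path.with_suffix(".hdr").read_text().splitlines())
    return LeadField(matrix=matrix, channel_names=tuple(hdr["channel_names"].split()),
                     n_generators=int(hdr["generators"]),
                     reference_applied=hdr["reference_applied"] == "True",
                     units=hdr["units"])


def write_ismaps(ismaps: list, space: SourceSpace, path) -> None:
    """Long-format source maps: generator, compartment, xyz, magnitude per row."""
    frames = []
    for m in ismaps:
        frames.append(pd.DataFrame({
            "subject": m.subject, "condition": m.condition,
            "component": m.component,
            "generator_id": np.arange(space.n_generators),
            "compartment": [space.atlas[int(k)] for k in space.compartment_labels],
            "x": space.positions[:, 0], "y": space.positions[:, 1],
            "z": space.positions[:, 2],
            "magnitude": m.magnitudes,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.17g")


def read_ismaps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
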