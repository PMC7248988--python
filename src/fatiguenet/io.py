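"""On-disk formats: recordings, KSS tables, segment sets, model checkpoints.

A recording is a plain CSV (one column per channel on the common clock) plus
a JSON sidecar ``<stem>.meta.json`` holding channel metadata (modality,
units, native rate), the common rate/duration and the session metadata —
a lossless, diff-able dialect.  Segment sets and model checkpoints use
``.npz`` arrays with a JSON manifest.  Every writer embeds the seed and a
config hash when provided, so artifacts can be replayed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cnn import FatigueCNN, ModelSpec
from .fusion import CaseConfig, FusedSegment, Normalizer, WindowSpec
from .labeling import KSSReport
from .signals import ChannelSpec, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_kss_table",
    "read_kss_table",
    "write_segments",
    "read_segments",
    "save_model",
    "load_model",
    "config_hash",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(recording: Recording, path: str | Path,
                    provenance: Optional[Dict[str, object]] = None) -> Path:
    path = Path(path)
    header = ",".join(c.name for c in recording.channels)
    np.savetxt(path, recording.samples.T, delimiter=",", header=header,
               comments="", fmt=_FLOAT_FMT)
    meta = {
        "rate": recording.rate,
        "duration": recording.duration,
        "channels": [
            {"name": c.name, "modality": c.modality,
             "native_rate": c.native_rate, "units": c.units}
            for c in recording.channels
        ],
        "session_meta": recording.session_meta,
    }
    if provenance:
        meta["provenance"] = provenance
    _meta_path(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise ValueError(f"missing sidecar metadata file {meta_file}")
    meta = json.loads(meta_file.read_text())
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError("no channels found") from None
    if table.shape[1] == 0 or not meta.get("channels"):
        raise ValueError("no channels found")

    channels: List[ChannelSpec] = []
    for c in meta["channels"]:
        channels.append(
            ChannelSpec(name=c["name"], modality=c["modality"],
                        native_rate=c["native_rate"], units=c.get("units", ""))
        )
    names = [c.name for c in channels]
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"recording file is missing channel column {missing[0]!r}")

    n = len(table)
    cols = []
    for name in names:
        col = table[name].to_numpy(dtype=np.float64)
        if np.isnan(col).any():
            raise ValueError(
                f"channel {name!r} is shorter than the others (NaN padding found)"
            )
        cols.append(col)
    samples = np.vstack(cols)
    expected = int(round(meta["rate"] * meta["duration"]))
    if n != expected:
        raise ValueError(
            f"sample count {n} does not match rate x duration = {expected}"
        )
    return Recording(
        channels=channels,
        samples=samples,
        rate=float(meta["rate"]),
        duration=float(meta["duration"]),
        session_meta=meta.get("session_meta", {}),
    )


def write_kss_table(reports: Sequence[KSSReport], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"subject_id": r.subject_id, "kss_pre": r.kss_pre, "kss_post": r.kss_post}
         for r in reports]
    )
    df.to_csv(path, index=False)
    return path


def read_kss_table(path: str | Path) -> List[KSSReport]:
    df = pd.read_csv(path)
    return [
        KSSReport(subject_id=str(row.subject_id), kss_pre=int(row.kss_pre),
                  kss_post=int(row.kss_post))
        for row in df.itertuples()
    ]


def write_segments(
    segments: Sequence[FusedSegment],
    path: str | Path,
    window: WindowSpec | None = None,
    case: CaseConfig | None = None,
    provenance: Optional[Dict[str, object]] = None,
) -> Path:
    path = Path(path)
    x = np.stack([s.matrix for s in segments])
    starts = np.array([s.start_time for s in segments])
    label_map = {"low": 0, "high": 1, None: -1}
    labels = np.array([label_map[s.label] for s in segments], dtype=np.int64)
    np.savez(path, matrices=x, start_times=starts, labels=labels)
    manifest = {
        "channel_order": list(segments[0].channel_order),
        "label_map": {"low": 0, "high": 1, "unknown": -1},
        "n_segments": len(segments),
    }
    if window is not None:
        manifest["window"] = {"length_s": window.length_s,
                              "overlap_s": window.overlap_s, "rate": window.rate}
    if case is not None:
        manifest["case_id"] = case.case_id
    if provenance:
        manifest["provenance"] = provenance
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    _meta_path(npz_path).write_text(json.dumps(manifest, indent=1, default=str))
    return npz_path


def read_segments(path: str | Path) -> List[FusedSegment]:
    path = Path(path)
    manifest = json.loads(_meta_path(path).read_text())
    data = np.load(path)
    inv = {0: "low", 1: "high", -1: None}
    return [
        FusedSegment(
            matrix=data["matrices"][i],
            start_time=float(data["start_times"][i]),
            channel_order=list(manifest["channel_order"]),
            label=inv[int(data["labels"][i])],
        )
        for i in range(int(manifest["n_segments"]))
    ]


def save_model(model: FatigueCNN, path: str | Path,
               normalizer: Optional[Normalizer] = None,
               provenance: Optional[Dict[str, object]] = None) -> Path:
    path = Path(path)
    arrays = dict(model.params)
    if normalizer is not None:
        arrays["__norm_mean"] = normalizer.mean_
        arrays["__norm_sd"] = normalizer.sd_
    np.savez(path, **arrays)
    manifest: Dict[str, object] = {
        "model_spec": model.spec.to_dict(),
        "init_seed": model.init_seed,
    }
    if normalizer is not None:
        manifest["normalizer_channels"] = list(normalizer.channel_order)
    if provenance:
        manifest["provenance"] = provenance
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    _meta_path(npz_path).write_text(json.dumps(manifest, indent=1, default=str))
    return npz_path


def load_model(path: str | Path):
    """Returns (model, normalizer-or-None)."""
    path = Path(path)
    manifest = json.loads(_meta_path(path).read_text())
    data = np.load(path)
    spec = ModelSpec.from_dict(manifest["model_spec"])
    model = FatigueCNN(spec, seed=int(manifest.get("init_seed", 0)))
    model.params = {k: data[k] for k in data.files if not k.startswith("__norm")}
    normalizer = None
    if "__norm_mean" in data.files:
        normalizer = Normalizer(
            mean_=data["__norm_mean"], sd_=data["__norm_sd"],
            channel_order=list(manifest["normalizer_channels"]),
        )
    return model, normalizer
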