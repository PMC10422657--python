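"""Plain-text persistence: record CSVs with JSON sidecars, window manifests
and feature-matrix CSVs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from mwppg.features import FeatureMatrix
from mwppg.signal_synth import MultiChannelRecord
from mwppg.windowing import WindowSet

PathLike = Union[str, Path]


def write_record_csv(record: MultiChannelRecord, path: PathLike, sidecar: bool = True) -> None:
    """Write ``time,green,red,ir,label_green,label_red,label_ir`` rows plus a
    JSON sidecar (``<path>.json``) with sample rate, seed and artifact manifest."""
    path = Path(path)
    data = {"time": record.times}
    for c in record.channel_names:
        data[c] = record.samples[c]
    for c in record.channel_names:
        data[f"label_{c}"] = record.labels[c]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        meta = {
            "sample_rate": record.sample_rate,
            "record_id": record.record_id,
            "channels": list(record.channel_names),
            **record.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=float)
        )


def read_record_csv(path: PathLike, sample_rate: Optional[float] = None) -> MultiChannelRecord:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if sample_rate is None:
        if "sample_rate" in meta:
            sample_rate = float(meta["sample_rate"])
        elif len(df) > 1:
            sample_rate = 1.0 / float(np.mean(np.diff(df["time"].to_numpy())))
        else:
            sample_rate = 125.0
    channels = tuple(meta.get("channels") or [c for c in df.columns if c not in ("time",) and not c.startswith("label_")])
    samples = {c: df[c].to_numpy(dtype=float) for c in channels}
    labels = {
        c: (
            df[f"label_{c}"].to_numpy(dtype=np.int8)
            if f"label_{c}" in df
            else np.zeros(len(df), dtype=np.int8)
        )
        for c in channels
    }
    rid = meta.get("record_id") or path.stem
    extra = {k: v for k, v in meta.items() if k not in ("sample_rate", "record_id", "channels")}
    return MultiChannelRecord(
        samples=samples, labels=labels, sample_rate=sample_rate,
        channel_names=channels, metadata=extra, record_id=rid,
    )


def write_window_manifest(ws: WindowSet, path: PathLike) -> None:
    rows = {
        "record_id": ws.record_ids,
        "start_sample": ws.starts,
        "window_samples": np.full(ws.n_windows, ws.window_samples),
    }
    for c in ws.channel_names:
        rows[f"label_{c}"] = ws.channel_labels[c]
    rows["label_sensor"] = ws.sensor_labels
    rows["split"] = ws.split if ws.split is not None else np.full(ws.n_windows, "", dtype=object)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_matrix(fm: FeatureMatrix, path: PathLike) -> None:
    fm.to_dataframe().to_csv(path, index=False)
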