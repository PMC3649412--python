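"""Delimited-text I/O for recordings, cue schedules and feature tables.

Recording format: CSV, first row channel ids, one row per sample; the sample
rate travels in a ``# sample_rate=<Hz>`` comment on the first line. Cue
schedules are CSV with columns ``onset_s, movement_label``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import FeatureVector, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_cue_schedule",
    "read_cue_schedule",
    "write_features",
    "read_features",
]


def write_recording(path: str | Path, recording: Recording) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={recording.sample_rate:g}\n")
        pd.DataFrame(recording.samples, columns=recording.channel_ids).to_csv(fh, index=False)


def read_recording(path: str | Path, subject_id: str = "") -> Recording:
    path = Path(path)
    sample_rate = 1000.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                if token.startswith("sample_rate="):
                    sample_rate = float(token.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    return Recording(
        samples=df.to_numpy(dtype=float),
        sample_rate=sample_rate,
        channel_ids=[str(c) for c in df.columns],
        subject_id=subject_id,
    )


def write_cue_schedule(path: str | Path, schedule) -> None:
    """``schedule``: iterable of (onset_s, movement_label) or an equivalent DataFrame."""
    if not isinstance(schedule, pd.DataFrame):
        schedule = pd.DataFrame(schedule, columns=["onset_s", "movement_label"])
    schedule.to_csv(path, index=False)


def read_cue_schedule(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"onset_s", "movement_label"} <= set(df.columns):
        raise ValueError("cue schedule needs columns onset_s, movement_label")
    return df[["onset_s", "movement_label"]]


def write_features(path: str | Path, features: list[FeatureVector]) -> None:
    rows = []
    for fv in features:
        row = {"label": fv.label if fv.label is not None else ""}
        row.update({cid: v for cid, v in zip(fv.channel_ids, fv.rms)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path, keep_default_na=False)
    channel_cols = [c for c in df.columns if c != "label"]
    out = []
    for _, row in df.iterrows():
        label = str(row["label"]) or None
        out.append(
            FeatureVector(
                rms=np.asarray([float(row[c]) for c in channel_cols]),
                channel_ids=channel_cols,
                label=label,
            )
        )
    return out
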