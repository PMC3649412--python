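"""Movement label <-> scalar network-output codec and session scoring.

The classifier regresses onto a single continuous output in [0, 1]; each of
the seven movements owns a fixed code. Decoding maps a continuous network
output gamma to the movement with the nearest code (ties break toward the
lower code), so the decision boundaries sit at code midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOVEMENT_CODES",
    "MOVEMENT_LABELS",
    "ABBREVIATIONS",
    "encode",
    "decode",
    "abbreviation",
    "SessionResult",
    "score_session",
    "aggregate",
    "confusion_matrix",
]

# (label, code, abbreviation) — codes are the fixed regression targets
MOVEMENT_CODES: list[tuple[str, float, str]] = [
    ("Hand Contraction", 0.0, "M0"),
    ("Wrist Extension", 0.083, "M1"),
    ("Wrist Flexion", 0.166, "M2"),
    ("Forearm Flexion", 0.249, "M3"),
    ("Forearm Rotation", 0.333, "M4"),
    ("Hand Abduction", 0.416, "M5"),
    ("Hand Adduction", 0.499, "M6"),
]

MOVEMENT_LABELS: list[str] = [m for m, _, _ in MOVEMENT_CODES]
ABBREVIATIONS: dict[str, str] = {m: a for m, _, a in MOVEMENT_CODES}
_CODES = np.array([c for _, c, _ in MOVEMENT_CODES])
_BY_LABEL = {m: c for m, c, _ in MOVEMENT_CODES}
_BY_ABBREV = {a: m for m, _, a in MOVEMENT_CODES}


def encode(label: str) -> float:
    """Scalar target code for a movement label (abbreviations M0-M6 accepted)."""
    label = _BY_ABBREV.get(label, label)
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown movement label {label!r}") from None


def decode(gamma: float) -> str:
    """Movement whose code is nearest to the network output ``gamma``.

    Ties break toward the lower code; any finite gamma outside the code range
    maps to the nearest endpoint class.
    """
    if not math.isfinite(gamma):
        raise ValueError(f"network output must be finite, got {gamma}")
    return MOVEMENT_LABELS[int(np.argmin(np.abs(_CODES - gamma)))]


def abbreviation(label: str) -> str:
    return ABBREVIATIONS[label]


@dataclass
class SessionResult:
    """Per-repetition classification outcomes for one session."""

    records: list[tuple[str, str, float]] = field(default_factory=list)  # (true, predicted, gamma)
    session_id: str = ""
    subject_id: str = ""

    def add(self, true_label: str, predicted_label: str, gamma: float) -> None:
        self.records.append((true_label, predicted_label, gamma))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["true", "predicted", "gamma"])
        df.insert(0, "session", self.session_id)
        df.insert(0, "subject", self.subject_id)
        return df


def score_session(session: SessionResult) -> dict[str, float]:
    """Per-movement hit rate in percent; movements absent from the session map to NaN."""
    hits: dict[str, int] = {m: 0 for m in MOVEMENT_LABELS}
    totals: dict[str, int] = {m: 0 for m in MOVEMENT_LABELS}
    for true, pred, _ in session.records:
        totals[true] += 1
        if pred == true:
            hits[true] += 1
    return {
        m: (100.0 * hits[m] / totals[m]) if totals[m] else float("nan")
        for m in MOVEMENT_LABELS
    }


def aggregate(session_rates: list[dict[str, float]], session_ids: list[str] | None = None) -> pd.DataFrame:
    """Stack per-session hit-rate rows into an accuracy table.

    Rows: one per session plus an ``Average`` row (per-movement mean over
    sessions); the ``Overall`` column of the average row is the mean over
    movements.
    """
    if not session_rates:
        raise ValueError("need at least one session")
    ids = session_ids or [f"Session {i}" for i in range(1, len(session_rates) + 1)]
    cols = [ABBREVIATIONS[m] for m in MOVEMENT_LABELS]
    table = pd.DataFrame(
        [[rates[m] for m in MOVEMENT_LABELS] for rates in session_rates],
        index=ids,
        columns=cols,
    )
    avg = table.mean(axis=0, skipna=True)
    table.loc["Average"] = avg
    table["Overall"] = float("nan")
    table.loc["Average", "Overall"] = float(avg.mean())
    return table


def confusion_matrix(sessions: list[SessionResult] | SessionResult) -> pd.DataFrame:
    """7x7 count matrix, rows = true movement, columns = predicted."""
    if isinstance(sessions, SessionResult):
        sessions = [sessions]
    abbrevs = [ABBREVIATIONS[m] for m in MOVEMENT_LABELS]
    mat = pd.DataFrame(0, index=abbrevs, columns=abbrevs, dtype=int)
    for s in sessions:
        for true, pred, _ in s.records:
            mat.loc[ABBREVIATIONS[true], ABBREVIATIONS[pred]] += 1
    return mat
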