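"""Surface-EMG preprocessing: from raw multi-channel recordings to per-window
RMS feature vectors.

The pipeline mirrors the standard myoelectric-control front end: per-channel
calibration, DC removal, 20-450 Hz band-pass, 60 Hz notch, cue-aligned
windowing, and a single RMS amplitude feature per channel per movement
execution. All filters are zero-phase (forward-backward Butterworth /
IIR-notch) so that window boundaries are not skewed by group delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "WindowSpec",
    "FeatureVector",
    "PreprocessingConfig",
    "remove_dc",
    "calibrate",
    "bandpass",
    "notch",
    "rms",
    "extract_windows",
    "featurize",
]

MAX_CHANNELS = 8


@dataclass
class Recording:
    """A fixed-rate multi-channel sEMG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signed amplitudes, volt-proportional arbitrary units.
    sample_rate : float
        Sampling rate in Hz (1000 Hz for the acquisition protocol modelled
        here).
    channel_ids : list of str
        Ordered channel labels, conventionally ``C0`` (biceps) .. ``C7``
        (extensor carpi ulnaris).
    subject_id : str
        Opaque subject label.
    """

    samples: np.ndarray
    sample_rate: float = 1000.0
    channel_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        n_ch = self.samples.shape[1]
        if not 1 <= n_ch <= MAX_CHANNELS:
            raise ValueError(f"channel count must be 1..{MAX_CHANNELS}, got {n_ch}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"C{i}" for i in range(n_ch)]
        if len(self.channel_ids) != n_ch:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def select_channels(self, channel_ids: list[str]) -> "Recording":
        """Return a new recording restricted to ``channel_ids`` (in that order)."""
        idx = [self.channel_ids.index(c) for c in channel_ids]
        return Recording(
            samples=self.samples[:, idx],
            sample_rate=self.sample_rate,
            channel_ids=list(channel_ids),
            subject_id=self.subject_id,
        )


@dataclass(frozen=True)
class WindowSpec:
    """A labelled time window [start, end) in seconds."""

    start: float
    end: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end})")


@dataclass
class FeatureVector:
    """Per-channel RMS amplitudes for one movement window — the classifier input."""

    rms: np.ndarray
    channel_ids: list[str]
    label: str | None = None

    def __post_init__(self) -> None:
        self.rms = np.asarray(self.rms, dtype=float)
        if self.rms.ndim != 1 or len(self.rms) != len(self.channel_ids):
            raise ValueError("rms length must match channel_ids")
        if np.any(self.rms < 0):
            raise ValueError("rms values must be non-negative")


@dataclass
class PreprocessingConfig:
    """Knobs for the preprocessing chain.

    ``calibration='rest'`` estimates a per-channel offset as the mean over
    ``rest_interval`` (seconds) with unit gain; ``'none'`` skips calibration.
    ``window_start`` / ``window_end`` place the analysis window relative to
    each cue onset: the default [0.4, 7.5] s spans the active portion of the
    8.3 s animation (ramp up, hold, ramp down), excluding the final rest.
    """

    band: tuple[float, float] = (20.0, 450.0)
    filter_order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 30.0
    calibration: str = "rest"  # 'rest' | 'none'
    rest_interval: tuple[float, float] = (0.0, 3.0)
    window_start: float = 0.4
    window_end: float = 7.5
    channels: list[str] | None = None  # subset selection, None = all


def remove_dc(signal: np.ndarray) -> np.ndarray:
    """Subtract the arithmetic mean of a single-channel signal."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove DC from an empty signal")
    return x - x.mean()


def calibrate(signal: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """Affine per-channel calibration: ``(signal - offset) * gain``."""
    if gain == 0:
        raise ValueError("calibration gain must be non-zero")
    return (np.asarray(signal, dtype=float) - offset) * gain


def _check_band(sample_rate: float, *freqs: float) -> None:
    nyq = sample_rate / 2.0
    for f in freqs:
        if not 0 < f < nyq:
            raise ValueError(f"cutoff {f} Hz outside (0, Nyquist={nyq}) at fs={sample_rate}")


def bandpass(
    signal: np.ndarray,
    sample_rate: float,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Removes motion artifacts / drift below ``low_hz`` and out-of-band noise
    above ``high_hz``; the surface-EMG energy of interest sits roughly in the
    70-300 Hz band and is preserved.
    """
    _check_band(sample_rate, low_hz, high_hz)
    if low_hz >= high_hz:
        raise ValueError("low_hz must be below high_hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def notch(
    signal: np.ndarray,
    sample_rate: float,
    f0_hz: float = 60.0,
    q: float = 30.0,
) -> np.ndarray:
    """Zero-phase IIR notch removing mains interference at ``f0_hz``."""
    _check_band(sample_rate, f0_hz)
    b, a = sps.iirnotch(f0_hz, q, fs=sample_rate)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=float))


def rms(segment: np.ndarray) -> float:
    """Root-mean-square amplitude of a one-channel segment."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty segment")
    return float(np.sqrt(np.mean(x**2)))


def extract_windows(
    recording: Recording,
    cue_schedule,
    window_start: float = 0.4,
    window_end: float = 7.5,
) -> list[WindowSpec]:
    """One analysis window per cued movement.

    ``cue_schedule`` is an iterable of ``(onset_s, label)`` pairs (or a
    DataFrame with those columns). Each window spans
    ``[onset + window_start, onset + window_end]``, clipped to the recording;
    cues entirely outside the recording are skipped with a warning.
    """
    pairs = _schedule_pairs(cue_schedule)
    duration = recording.duration
    windows: list[WindowSpec] = []
    for onset, label in pairs:
        start, end = onset + window_start, onset + window_end
        if start >= duration:
            logger.warning("cue at %.3f s falls outside the %.3f s recording; skipped", onset, duration)
            continue
        if end > duration:
            logger.warning("window for cue at %.3f s clipped to recording end (%.3f s)", onset, duration)
            end = duration
        windows.append(WindowSpec(start=start, end=end, label=label))
    return windows


def _schedule_pairs(cue_schedule) -> list[tuple[float, str]]:
    if hasattr(cue_schedule, "itertuples"):  # DataFrame with onset_s, movement_label
        return [(float(r.onset_s), str(r.movement_label)) for r in cue_schedule.itertuples()]
    return [(float(t), str(lab)) for t, lab in cue_schedule]


def featurize(
    recording: Recording,
    cue_schedule,
    config: PreprocessingConfig | None = None,
) -> list[FeatureVector]:
    """Run the full chain calibrate -> remove DC -> band-pass -> notch ->
    window -> per-channel RMS; returns one labelled feature vector per cue."""
    cfg = config or PreprocessingConfig()
    rec = recording
    if cfg.channels is not None:
        rec = rec.select_channels(cfg.channels)
    fs = rec.sample_rate

    cleaned = np.empty_like(rec.samples)
    for c in range(rec.n_channels):
        x = rec.samples[:, c]
        if cfg.calibration == "rest":
            i0 = int(round(cfg.rest_interval[0] * fs))
            i1 = int(round(cfg.rest_interval[1] * fs))
            rest = x[i0:max(i1, i0 + 1)]
            x = calibrate(x, gain=1.0, offset=float(rest.mean()))
        elif cfg.calibration != "none":
            raise ValueError(f"unknown calibration mode {cfg.calibration!r}")
        x = remove_dc(x)
        x = bandpass(x, fs, cfg.band[0], cfg.band[1], order=cfg.filter_order)
        x = notch(x, fs, cfg.notch_hz, cfg.notch_q)
        cleaned[:, c] = x

    windows = extract_windows(rec, cue_schedule, cfg.window_start, cfg.window_end)
    features: list[FeatureVector] = []
    for w in windows:
        i0, i1 = int(round(w.start * fs)), int(round(w.end * fs))
        seg = cleaned[i0:i1]
        features.append(
            FeatureVector(
                rms=np.sqrt(np.mean(seg**2, axis=0)),
                channel_ids=list(rec.channel_ids),
                label=w.label,
            )
        )
    return features
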