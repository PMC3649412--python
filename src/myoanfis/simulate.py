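"""Synthetic 8-channel surface-EMG session generator.

Real sEMG during a sustained contraction is well approximated by band-limited
Gaussian noise whose envelope tracks muscle activation (the classic
interference-pattern model). Each simulated channel is

    dc_offset + mains 60 Hz sine
    + band-limited unit-RMS noise * (rest_noise_rms + gain[movement, ch] * a(t))

where ``a(t)`` is a trapezoidal activation profile following the cue
animation timing: 0.4 s rest, 2.9 s ramp up (forward movement), 1.25 s hold,
2.9 s ramp down (backward movement), 0.8 s rest — 8.3 s total — and
``gain`` is the movement x channel activation map derived from the
channel/muscle assignment (each movement drives one primary channel at gain
1.0, physiologically coupled channels at a configurable crosstalk gain, all
others at a small baseline).

Sessions follow the acquisition protocol: 5 repetitions of each of the 7
movements in seeded-random order, 3 s rest between movements, 5 sessions per
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .codec import MOVEMENT_LABELS
from .preprocessing import Recording

__all__ = [
    "Protocol",
    "ActivationMap",
    "NoiseModel",
    "default_activation_map",
    "activation_profile",
    "generate_movement",
    "generate_session",
    "generate_subject",
]

CHANNEL_IDS = [f"C{i}" for i in range(8)]

# channel/muscle assignment: movement -> primary channel
PRIMARY_CHANNEL: dict[str, str] = {
    "Forearm Flexion": "C0",  # biceps
    "Hand Abduction": "C1",  # flexor carpi ulnaris
    "Hand Adduction": "C2",  # flexor carpi radialis
    "Hand Contraction": "C3",  # extensor digitorum
    "Forearm Rotation": "C4",  # pronator teres (brachioradialis C5 assists)
    "Wrist Flexion": "C6",  # palmaris longus
    "Wrist Extension": "C7",  # extensor carpi ulnaris
}

# channels shared between forearm flexion (M3) and forearm rotation (M4):
# biceps (C0), pronator teres (C4) and brachioradialis (C5) all participate in
# both movements, which is the anatomical source of the M3/M4 confusion.
_COUPLED = {
    "Forearm Flexion": ["C4", "C5"],
    "Forearm Rotation": ["C0", "C5"],
}


@dataclass
class Protocol:
    """Cue animation timing and session layout (seconds / counts).

    The 1.3 s hold covers the 1.25 s static movement interval plus the
    animation frame padding, so the total animation lasts exactly 8.3 s and
    the active portion (ramp up, hold, ramp down) ends 7.5 s after the cue.
    """

    initial_rest: float = 0.4
    forward: float = 2.9
    hold: float = 1.3
    backward: float = 2.9
    final_rest: float = 0.8
    inter_movement_rest: float = 3.0
    reps_per_movement: int = 5
    sessions: int = 5
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("initial_rest", "forward", "hold", "backward", "final_rest",
                     "inter_movement_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def animation_duration(self) -> float:
        """Total cue animation length (8.3 s at defaults)."""
        return self.initial_rest + self.forward + self.hold + self.backward + self.final_rest

    @property
    def movements_per_session(self) -> int:
        return self.reps_per_movement * len(MOVEMENT_LABELS)

    def session_duration(self) -> float:
        """Leading rest plus one (animation + rest) block per movement."""
        n = self.movements_per_session
        return self.inter_movement_rest + n * (self.animation_duration + self.inter_movement_rest)


@dataclass
class ActivationMap:
    """7x8 movement-by-channel gain matrix in [0, 1]."""

    gains: pd.DataFrame  # index = movement labels, columns = channel ids

    def __post_init__(self) -> None:
        g = self.gains.to_numpy(dtype=float)
        if np.any((g < 0) | (g > 1)):
            raise ValueError("gains must lie in [0, 1]")
        if not np.all((g == 1.0).sum(axis=1) == 1):
            raise ValueError("each movement must have exactly one gain of 1.0")

    def gain(self, movement: str, channel: str) -> float:
        return float(self.gains.loc[movement, channel])

    def row(self, movement: str) -> np.ndarray:
        return self.gains.loc[movement].to_numpy(dtype=float)


def default_activation_map(crosstalk: float = 0.4, baseline: float = 0.05) -> ActivationMap:
    """Activation map from the channel/muscle assignment.

    ``crosstalk`` is the gain on the shared-muscle channels of the forearm
    flexion / rotation pair; raising it toward 1 makes those two movements
    progressively indistinguishable. ``baseline`` is the co-activation level
    of all uninvolved channels.
    """
    gains = pd.DataFrame(baseline, index=MOVEMENT_LABELS, columns=CHANNEL_IDS, dtype=float)
    for movement, channel in PRIMARY_CHANNEL.items():
        gains.loc[movement, channel] = 1.0
    for movement, coupled in _COUPLED.items():
        for channel in coupled:
            gains.loc[movement, channel] = crosstalk
    return ActivationMap(gains=gains)


@dataclass
class NoiseModel:
    """Amplitudes of the simulated interference sources."""

    emg_band: tuple[float, float] = (20.0, 450.0)
    rest_noise_rms: float = 0.05
    mains_amplitude: float = 0.1
    mains_hz: float = 60.0
    dc_offset: np.ndarray | float = 0.1

    def __post_init__(self) -> None:
        if self.rest_noise_rms < 0 or self.mains_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")

    def dc_for(self, n_channels: int) -> np.ndarray:
        dc = np.asarray(self.dc_offset, dtype=float)
        if dc.ndim == 0:
            return np.full(n_channels, float(dc))
        return dc[:n_channels]


def activation_profile(t, protocol: Protocol | None = None):
    """Trapezoidal activation in [0, 1] at time(s) ``t`` within one animation."""
    p = protocol or Protocol()
    t = np.asarray(t, dtype=float)
    t0 = p.initial_rest
    t1 = t0 + p.forward
    t2 = t1 + p.hold
    t3 = t2 + p.backward
    up = np.clip((t - t0) / p.forward, 0.0, 1.0)
    down = np.clip((t3 - t) / p.backward, 0.0, 1.0)
    prof = np.where(t < t1, up, np.where(t <= t2, 1.0, down))
    prof = np.where((t < t0) | (t > t3), 0.0, prof)
    return float(prof) if prof.ndim == 0 else prof


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise normalized to unit RMS."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    scale = np.sqrt(np.mean(x**2))
    return x / scale if scale > 0 else x


def _movement_block(
    movement: str,
    protocol: Protocol,
    amap: ActivationMap,
    noise: NoiseModel,
    rng: np.random.Generator,
    amplitude_jitter: float = 0.0,
) -> np.ndarray:
    n = int(round(protocol.animation_duration * protocol.sample_rate))
    t = np.arange(n) / protocol.sample_rate
    prof = activation_profile(t, protocol)
    gains = amap.row(movement)
    if amplitude_jitter > 0:
        gains = gains * (1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter))
    dc = noise.dc_for(len(gains))
    mains = noise.mains_amplitude * np.sin(2 * np.pi * noise.mains_hz * t)
    block = np.empty((n, len(gains)))
    for c, g in enumerate(gains):
        envelope = noise.rest_noise_rms + g * prof
        block[:, c] = dc[c] + mains + envelope * _band_noise(n, protocol.sample_rate, noise.emg_band, rng)
    return block


def _rest_block(
    duration: float,
    protocol: Protocol,
    noise: NoiseModel,
    rng: np.random.Generator,
    n_channels: int = 8,
) -> np.ndarray:
    n = int(round(duration * protocol.sample_rate))
    t = np.arange(n) / protocol.sample_rate
    dc = noise.dc_for(n_channels)
    mains = noise.mains_amplitude * np.sin(2 * np.pi * noise.mains_hz * t)
    block = np.empty((n, n_channels))
    for c in range(n_channels):
        block[:, c] = dc[c] + mains + noise.rest_noise_rms * _band_noise(
            n, protocol.sample_rate, noise.emg_band, rng
        )
    return block


def generate_movement(
    movement: str,
    protocol: Protocol | None = None,
    activation_map: ActivationMap | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    amplitude_jitter: float = 0.0,
) -> tuple[Recording, tuple[float, str]]:
    """One isolated 8.3 s movement execution.

    Returns the recording and its cue-schedule entry ``(onset_s=0, label)``.
    Deterministic for a fixed seed.
    """
    if movement not in MOVEMENT_LABELS:
        raise ValueError(f"unknown movement {movement!r}")
    p = protocol or Protocol()
    amap = activation_map or default_activation_map()
    noise = noise_model or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    block = _movement_block(movement, p, amap, noise, rng, amplitude_jitter)
    rec = Recording(samples=block, sample_rate=p.sample_rate, channel_ids=list(CHANNEL_IDS))
    return rec, (0.0, movement)


def generate_session(
    protocol: Protocol | None = None,
    activation_map: ActivationMap | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    session_index: int = 0,
    subject_id: str = "synthetic",
    amplitude_jitter: float = 0.0,
) -> tuple[Recording, pd.DataFrame]:
    """One full session: every movement repeated ``reps_per_movement`` times in
    seeded-random order, separated by inter-movement rests.

    Returns the concatenated recording and a cue schedule DataFrame with
    columns ``onset_s, movement_label`` (onsets mark animation starts).
    """
    p = protocol or Protocol()
    amap = activation_map or default_activation_map()
    noise = noise_model or NoiseModel()
    ss = np.random.SeedSequence([seed, session_index])
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    labels = np.repeat(MOVEMENT_LABELS, p.reps_per_movement)
    order = order_rng.permutation(len(labels))
    sequence = [labels[i] for i in order]

    rep_seeds = ss.spawn(len(sequence) + 1)
    blocks = [_rest_block(p.inter_movement_rest, p, noise, np.random.default_rng(rep_seeds[0]))]
    onsets: list[float] = []
    t = p.inter_movement_rest
    for k, movement in enumerate(sequence):
        rng = np.random.default_rng(rep_seeds[k + 1])
        blocks.append(_movement_block(movement, p, amap, noise, rng, amplitude_jitter))
        onsets.append(t)
        t += p.animation_duration
        blocks.append(_rest_block(p.inter_movement_rest, p, noise, rng))
        t += p.inter_movement_rest

    rec = Recording(
        samples=np.vstack(blocks),
        sample_rate=p.sample_rate,
        channel_ids=list(CHANNEL_IDS),
        subject_id=subject_id,
    )
    schedule = pd.DataFrame({"onset_s": onsets, "movement_label": sequence})
    return rec, schedule


def generate_subject(
    protocol: Protocol | None = None,
    activation_map: ActivationMap | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    subject_id: str = "synthetic",
    amplitude_jitter: float = 0.0,
) -> list[tuple[Recording, pd.DataFrame]]:
    """All sessions of one subject (5 at defaults); session 1 is conventionally
    the training session, the rest are evaluation sessions."""
    p = protocol or Protocol()
    return [
        generate_session(
            p,
            activation_map,
            noise_model,
            seed=seed,
            session_index=s,
            subject_id=subject_id,
            amplitude_jitter=amplitude_jitter,
        )
        for s in range(p.sessions)
    ]
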