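"""Synthetic multichannel EEG with the statistical structure the analyses assume.

The simulator renders a :class:`~tripletseg.stimuli.SessionSchedule` into a
channels-by-samples voltage array:

* a syllable-evoked kernel convolved with every syllable onset (the 4 Hz
  steady-state response),
* a word-onset kernel active only inside structured segments and gated by a
  sigmoid learning curve (the emergent 1.33 Hz component),
* condition-dependent responses to isolated test words (an early additive
  component distinguishing ABx from BCx triplets, optionally a late one),
* spatially mixed 1/f background noise, white sensor noise, and occasional
  high-amplitude artifact excursions.

All randomness flows from ``config.seed``; identical configs give bit-identical
arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .stimuli import (
    SYLLABLE_DURATION,
    WORD_DURATION,
    SessionSchedule,
    events_frame,
)

__all__ = [
    "MontageSpec",
    "SimulationConfig",
    "Recording",
    "make_montage",
    "simulate_recording",
]

ABX_CONDITIONS = ("Word", "EdgeWord")
BCX_CONDITIONS = ("PartWord", "NonWord")


@dataclass(frozen=True)
class MontageSpec:
    """Channel ids and 3D positions (cm) on an upper hemisphere."""

    channels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) cm
    reference: str
    head_radius: float

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.positions):
            raise ValueError("channel/position length mismatch")
        if np.any(self.positions[:, 2] < -1e-9):
            raise ValueError("all channels must lie above the equatorial plane")

    def __len__(self) -> int:
        return len(self.channels)

    def distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channels,
                "x_cm": self.positions[:, 0],
                "y_cm": self.positions[:, 1],
                "z_cm": self.positions[:, 2],
                "is_reference": [c == self.reference for c in self.channels],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, head_radius: float | None = None) -> "MontageSpec":
        pos = df[["x_cm", "y_cm", "z_cm"]].to_numpy(float)
        ref_rows = df.index[df["is_reference"].astype(bool)]
        ref = str(df.loc[ref_rows[0], "channel"]) if len(ref_rows) else str(df["channel"].iloc[0])
        if head_radius is None:
            head_radius = float(np.linalg.norm(pos, axis=1).max())
        return cls(
            channels=tuple(str(c) for c in df["channel"]),
            positions=pos,
            reference=ref,
            head_radius=head_radius,
        )


def make_montage(n_channels: int, head_radius: float = 10.5, seed: int = 0) -> MontageSpec:
    """Quasi-uniform electrode positions on the upper hemisphere.

    A Fibonacci lattice restricted to z >= 0 is used; ``seed`` sets a random
    azimuthal rotation so distinct montages can be drawn at the same size.
    Deterministic given its arguments.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    if head_radius <= 0:
        raise ValueError("head radius must be positive")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # cos(theta) in (0, 1): upper hemisphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    azimuth = golden * i + phase
    r_xy = np.sqrt(1.0 - z**2)
    pos = head_radius * np.stack(
        [r_xy * np.cos(azimuth), r_xy * np.sin(azimuth), z], axis=1
    )
    channels = tuple(f"E{k + 1:03d}" for k in range(n_channels))
    return MontageSpec(
        channels=channels, positions=pos, reference=channels[0], head_radius=head_radius
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG generator (amplitudes in µV)."""

    sampling_rate: float = 250.0
    # syllable-evoked kernel (damped sinusoid)
    syllable_amplitude: float = 4.0
    syllable_kernel_freq: float = 5.0
    syllable_kernel_decay: float = 0.06
    syllable_kernel_latency: float = 0.05
    # emergent word-rate component
    word_rate_amplitude: float = 3.0
    word_kernel_freq: float = 1.8
    word_kernel_decay: float = 0.2
    learning_onset_s: float = 120.0
    learning_ramp_s: float = 20.0
    # test-word ERPs
    erp_base_amplitude: float = 3.0
    erp_effect_amplitude: float = 2.0
    erp_effect_window: tuple[float, float] = (0.0, 0.4)
    erp_late_effect_amplitude: float = 0.0
    erp_late_effect_window: tuple[float, float] = (0.8, 1.6)
    # noise model
    pink_exponent: float = 1.0
    pink_scale: float = 15.0
    white_scale: float = 4.0
    n_noise_sources: int = 10
    # artifacts
    artifact_rate_per_min: float = 0.0
    artifact_amplitude: float = 800.0
    artifact_duration_s: float = 0.4
    seed: int = 0
    # topographies of the evoked components; share this across a simulated
    # cohort so group-level spatial statistics see a consistent effect
    # (None: derived from ``seed``)
    topography_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "syllable_amplitude",
            "word_rate_amplitude",
            "erp_base_amplitude",
            "erp_effect_amplitude",
            "erp_late_effect_amplitude",
            "pink_scale",
            "white_scale",
            "artifact_amplitude",
            "artifact_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.learning_onset_s < 0:
            raise ValueError("learning_onset_s must be >= 0")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["erp_effect_window"] = list(self.erp_effect_window)
        d["erp_late_effect_window"] = list(self.erp_late_effect_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("erp_effect_window", "erp_late_effect_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Recording:
    """Multichannel time series plus events table and montage."""

    data: np.ndarray  # (channels, samples), µV
    sampling_rate: float
    events: pd.DataFrame
    montage: MontageSpec

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError("data must be (channels, samples) matching montage")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def segment_table(self) -> pd.DataFrame:
        seg = self.events[self.events["kind"] == "segment"]
        return seg.reset_index(drop=True)

    def test_event_table(self) -> pd.DataFrame:
        ev = self.events
        first = (ev["kind"] == "syllable") & (ev["segment_kind"] == "TestBlock") & (
            ev["position"] == 1
        )
        return ev[first].reset_index(drop=True)


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------


def _damped_sinusoid(
    rate: float, freq: float, decay: float, latency: float, duration: float = 0.6
) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate - latency
    k = np.sin(2 * np.pi * freq * t) * np.exp(-t / decay)
    k[t < 0] = 0.0
    return k


def _bump(rate: float, window: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Half-cosine bump over ``window`` (s); returns kernel and offset samples."""
    t0, t1 = window
    n = max(int(round((t1 - t0) * rate)), 1)
    x = np.linspace(0, np.pi, n)
    return np.sin(x), int(round(t0 * rate))


def _smooth_map(montage: MontageSpec, rng: np.random.Generator, sigma: float = 0.6) -> np.ndarray:
    """Random smooth topography: dipolar pair of Gaussian blobs on the sphere."""
    pos = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    w = np.zeros(len(montage))
    for sign in (1.0, -1.0):
        center = rng.normal(size=3)
        center[2] = abs(center[2])
        center /= np.linalg.norm(center)
        ang = np.arccos(np.clip(pos @ center, -1, 1))
        w += sign * np.exp(-(ang**2) / (2 * sigma**2))
    w /= np.max(np.abs(w))
    return w


def _add_kernel(data: np.ndarray, topo: np.ndarray, kernel: np.ndarray,
                sample: int, gain: float = 1.0) -> None:
    n = data.shape[1]
    if sample >= n or sample + len(kernel) <= 0:
        return
    a = max(sample, 0)
    b = min(sample + len(kernel), n)
    data[:, a:b] += gain * np.outer(topo, kernel[a - sample : b - sample])


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f**exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _structured_exposure_offsets(schedule: SessionSchedule) -> dict[float, float]:
    """Map structured-segment start -> cumulative structured seconds before it."""
    out = {}
    acc = 0.0
    for seg in schedule.segments:
        if seg.kind == "StructuredStream":
            out[seg.start_s] = acc
            acc += seg.duration_s
    return out


def simulate_recording(
    schedule: SessionSchedule, montage: MontageSpec, config: SimulationConfig
) -> Recording:
    """Render a schedule into a synthetic multichannel recording.

    See the module docstring for the signal model.  The returned events table
    is the schedule's events sidecar, so downstream stages can be driven from
    the recording alone.
    """
    rate = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    n_ch = len(montage)
    n_samp = int(np.ceil(schedule.total_duration * rate))
    data = np.zeros((n_ch, n_samp))

    topo_seed = config.topography_seed if config.topography_seed is not None else config.seed
    rng_topo = np.random.default_rng(topo_seed)
    topo_syll = _smooth_map(montage, rng_topo)
    topo_word = _smooth_map(montage, rng_topo)
    topo_erp = _smooth_map(montage, rng_topo)
    topo_late = _smooth_map(montage, rng_topo)

    k_syll = _damped_sinusoid(
        rate, config.syllable_kernel_freq, config.syllable_kernel_decay,
        config.syllable_kernel_latency, duration=0.5,
    )
    k_word = _damped_sinusoid(
        rate, config.word_kernel_freq, config.word_kernel_decay,
        config.syllable_kernel_latency, duration=WORD_DURATION,
    )
    k_erp, erp_off = _bump(rate, config.erp_effect_window)
    k_late, late_off = _bump(rate, config.erp_late_effect_window)

    exposure = _structured_exposure_offsets(schedule)

    # (a) syllable-evoked response at every syllable onset (streams + tests)
    if config.syllable_amplitude > 0:
        for seg in schedule.segments:
            if seg.kind in ("RandomStream", "StructuredStream"):
                for onset in seg.payload.onsets:
                    s = int(round((seg.start_s + onset) * rate))
                    _add_kernel(data, topo_syll, k_syll, s, config.syllable_amplitude)
            elif seg.kind == "TestBlock":
                for ev in seg.payload:
                    for p in range(3):
                        s = int(round((ev.onset_s + p * SYLLABLE_DURATION) * rate))
                        _add_kernel(data, topo_syll, k_syll, s, config.syllable_amplitude)

    # (b) word-rate component, sigmoid-gated by cumulative structured exposure
    if config.word_rate_amplitude > 0:
        for seg in schedule.segments:
            if seg.kind != "StructuredStream":
                continue
            base = exposure[seg.start_s]
            for onset in seg.payload.word_onsets():
                exp_t = base + onset
                if config.learning_ramp_s > 0:
                    gate = 1.0 / (
                        1.0 + np.exp(-(exp_t - config.learning_onset_s) / config.learning_ramp_s)
                    )
                else:
                    gate = float(exp_t >= config.learning_onset_s)
                s = int(round((seg.start_s + onset) * rate))
                _add_kernel(data, topo_word, k_word, s, config.word_rate_amplitude * gate)

    # (c) test-word ERPs: base response plus condition-dependent early component
    for ev in schedule.test_events:
        s = int(round(ev.onset_s * rate))
        if config.erp_base_amplitude > 0:
            _add_kernel(data, topo_erp, k_erp, s + erp_off, config.erp_base_amplitude)
        is_abx = ev.test_word.condition in ABX_CONDITIONS
        if config.erp_effect_amplitude > 0 and is_abx:
            _add_kernel(data, topo_erp, k_erp, s + erp_off, config.erp_effect_amplitude)
        if config.erp_late_effect_amplitude > 0 and is_abx:
            _add_kernel(data, topo_late, k_late, s + late_off, config.erp_late_effect_amplitude)

    # (d) 1/f background, independent sources mixed to channels
    if config.pink_scale > 0:
        for _ in range(config.n_noise_sources):
            topo = _smooth_map(montage, rng)
            src = _pink_noise(n_samp, config.pink_exponent, rng)
            data += (config.pink_scale / np.sqrt(config.n_noise_sources)) * np.outer(topo, src)

    # (e) white sensor noise
    if config.white_scale > 0:
        data += config.white_scale * rng.normal(size=data.shape)

    # (f) artifact excursions at Poisson times
    if config.artifact_rate_per_min > 0:
        n_art = rng.poisson(config.artifact_rate_per_min * schedule.total_duration / 60.0)
        width = int(round(config.artifact_duration_s * rate))
        for _ in range(n_art):
            s = int(rng.integers(0, max(n_samp - width, 1)))
            ch = rng.integers(0, n_ch)
            shape = np.hanning(width) if rng.uniform() < 0.5 else np.ones(width)
            data[ch, s : s + width] += config.artifact_amplitude * shape[: n_samp - s]

    return Recording(
        data=data,
        sampling_rate=rate,
        events=events_frame(schedule),
        montage=montage,
    )
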