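"""Filtering, resampling, epoching, artifact rejection and normalization.

Two canonical pipelines are provided on top of the individual operations:

* entrainment: band-pass 0.1--40 Hz -> resample 300 Hz -> high-pass 0.2 Hz ->
  0.75 s consecutive epochs from each phase onset -> peak-to-peak rejection;
* ERP: band-pass 0.5--20 Hz -> [-1.50, 3.25] s epochs around test-word onsets
  -> rejection -> average reference -> per-epoch normalization -> baseline
  correction.

All filters are zero-phase (forward-backward Butterworth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Recording

__all__ = [
    "EpochSet",
    "bandpass",
    "highpass",
    "resample",
    "epoch",
    "segment_epochs",
    "reject_epochs",
    "average_reference",
    "normalize_epochs",
    "baseline_correct",
    "preprocess_entrainment",
    "preprocess_erp",
    "save_epochs",
    "load_epochs",
    "DEFAULT_REJECT_UV",
]

DEFAULT_REJECT_UV = 400.0
"""Default peak-to-peak rejection threshold (µV), applied pre-normalization."""

STREAM_KINDS = ("RestingState", "RandomStream", "StructuredStream")


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch metadata.

    ``data`` is (epochs, channels, samples).  ``onsets`` are epoch start times
    in recording seconds (the sample at relative time ``tmin``).
    ``rejection_mask`` (when set) is a boolean over the pre-rejection epochs,
    ``True`` for retained ones.
    """

    data: np.ndarray
    sampling_rate: float
    onsets: np.ndarray
    metadata: pd.DataFrame
    tmin: float = 0.0
    rejection_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        n = self.data.shape[0]
        if len(self.onsets) != n or len(self.metadata) != n:
            raise ValueError("metadata/onsets length must equal epoch count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sampling_rate

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            data=self.data[idx],
            onsets=self.onsets[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            rejection_mask=None,
        )


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(recording: Recording, low: float, high: float,
             order_low: int = 4, order_high: int = 8) -> Recording:
    """Zero-phase Butterworth band-pass; removes DC.

    Implemented as separate high-pass and low-pass sections so each edge can
    be steep enough (forward-backward order-8 low-pass attenuates a tone half
    an octave above the edge by > 20 dB).
    """
    nyq = recording.sampling_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band [{low}, {high}] Hz for rate {recording.sampling_rate}")
    sos_hp = signal.butter(order_low, low, btype="highpass",
                           fs=recording.sampling_rate, output="sos")
    sos_lp = signal.butter(order_high, high, btype="lowpass",
                           fs=recording.sampling_rate, output="sos")
    data = _sos_filtfilt(_sos_filtfilt(recording.data, sos_hp), sos_lp)
    return replace(recording, data=data)


def highpass(recording: Recording, low: float, order: int = 4) -> Recording:
    nyq = recording.sampling_rate / 2
    if not 0 < low < nyq:
        raise ValueError(f"invalid high-pass edge {low} Hz")
    sos = signal.butter(order, low, btype="highpass", fs=recording.sampling_rate, output="sos")
    return replace(recording, data=_sos_filtfilt(recording.data, sos))


def resample(recording: Recording, new_rate: float) -> Recording:
    """Polyphase anti-aliased resampling; event times stay in seconds."""
    if new_rate <= 0:
        raise ValueError("sampling rate must be positive")
    if abs(new_rate - recording.sampling_rate) < 1e-12:
        return recording
    frac = Fraction(new_rate / recording.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=-1)
    return replace(recording, data=out, sampling_rate=new_rate)


def epoch(
    recording: Recording,
    onsets: np.ndarray,
    tmin: float,
    tmax: float,
    metadata: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut epochs spanning ``[onset + tmin, onset + tmax)`` seconds.

    Epochs that would exceed the data bounds are dropped with a warning.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be below tmax")
    rate = recording.sampling_rate
    onsets = np.asarray(onsets, dtype=float)
    n_samp = int(round((tmax - tmin) * rate))
    starts = np.round((onsets + tmin) * rate).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= recording.n_samples)
    if not ok.all():
        warnings.warn(f"dropping {np.sum(~ok)} epochs exceeding data bounds")
    if not ok.any():
        raise ValueError("no epoch fits within the recording")
    starts = starts[ok]
    data = np.stack([recording.data[:, s : s + n_samp] for s in starts])
    if metadata is None:
        metadata = pd.DataFrame(index=range(len(starts)))
    else:
        metadata = metadata.iloc[np.flatnonzero(ok)].reset_index(drop=True)
    return EpochSet(
        data=data,
        sampling_rate=rate,
        onsets=onsets[ok],
        metadata=metadata,
        tmin=tmin,
    )


def segment_epochs(
    recording: Recording,
    kinds: tuple[str, ...] = STREAM_KINDS,
    length: float = 0.75,
) -> EpochSet:
    """Consecutive ``length``-second epochs from the start of each segment.

    Only whole epochs fitting inside a segment are produced; metadata records
    the segment kind, segment start and a chronological epoch index.
    """
    segs = recording.segment_table()
    onsets, rows = [], []
    for _, seg in segs.iterrows():
        if seg["segment_kind"] not in kinds:
            continue
        n = int(np.floor(seg["duration_s"] / length + 1e-9))
        for j in range(n):
            onsets.append(seg["onset_s"] + j * length)
            rows.append(
                {
                    "segment_kind": seg["segment_kind"],
                    "segment_start_s": seg["onset_s"],
                    "segment_duration_s": seg["duration_s"],
                    "index_in_segment": j,
                }
            )
    if not onsets:
        raise ValueError(f"no segments of kinds {kinds} in recording")
    md = pd.DataFrame(rows)
    es = epoch(recording, np.asarray(onsets), 0.0, length, metadata=md)
    es.metadata["epoch_index"] = np.arange(len(es))
    return es


def reject_epochs(epochs: EpochSet, peak_to_peak_threshold: float = DEFAULT_REJECT_UV) -> EpochSet:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold on any channel."""
    if peak_to_peak_threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)
    keep = (ptp <= peak_to_peak_threshold).all(axis=1)
    if not keep.any():
        raise ValueError(
            "all epochs rejected; consider raising the peak-to-peak threshold "
            f"(currently {peak_to_peak_threshold} µV)"
        )
    out = epochs.select(keep)
    out.rejection_mask = keep
    return out


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous channel mean from every sample."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def normalize_epochs(epochs: EpochSet) -> EpochSet:
    """Divide each epoch by its standard deviation pooled over channels and samples."""
    sd = epochs.data.std(axis=(1, 2))
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance epochs at indices {bad.tolist()}")
    return replace(epochs, data=epochs.data / sd[:, None, None])


def baseline_correct(epochs: EpochSet, window) -> EpochSet:
    """Subtract the per-channel mean over a baseline window.

    ``window`` is either a single ``(t0, t1)`` pair in epoch time or an
    (n_epochs, 2) array of per-epoch windows.
    """
    win = np.asarray(window, dtype=float)
    if win.ndim == 1:
        win = np.broadcast_to(win, (len(epochs), 2))
    data = epochs.data.copy()
    rate = epochs.sampling_rate
    for i in range(len(epochs)):
        a = int(round((win[i, 0] - epochs.tmin) * rate))
        b = int(round((win[i, 1] - epochs.tmin) * rate))
        a, b = max(a, 0), min(max(b, a + 1), epochs.n_samples)
        data[i] -= data[i, :, a:b].mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


# ---------------------------------------------------------------------------
# canonical pipelines
# ---------------------------------------------------------------------------


def preprocess_entrainment(
    recording: Recording,
    reject_uv: float = DEFAULT_REJECT_UV,
    target_rate: float = 300.0,
) -> EpochSet:
    """Entrainment pipeline producing retained 0.75 s epochs.

    Band-pass 0.1--40 Hz, resample so a triplet holds an integer number of
    samples (225 at 300 Hz), high-pass 0.2 Hz, epoch each phase in
    consecutive 0.75 s segments, reject by peak-to-peak amplitude.
    """
    rec = bandpass(recording, 0.1, 40.0)
    rec = resample(rec, target_rate)
    rec = highpass(rec, 0.2)
    epochs = segment_epochs(rec, STREAM_KINDS, 0.75)
    return reject_epochs(epochs, reject_uv)


def _baseline_windows(ev: pd.DataFrame, mode: str) -> np.ndarray:
    """Per-epoch baseline windows in epoch-relative time.

    ``mode="gap"`` (default): from 2.25 s after the previous word's onset up
    to the current word's onset; the first word of a block falls back to
    [-0.25, 0] s.  ``mode="span"``: a 2.25 s window starting at the previous
    word's onset.
    """
    wins = np.empty((len(ev), 2))
    prev_onset = None
    prev_block = None
    for i, row in enumerate(ev.itertuples()):
        if prev_block != row.block:
            prev_onset = None
        if prev_onset is None:
            wins[i] = (-0.25, 0.0)
        elif mode == "gap":
            wins[i] = (prev_onset + 2.25 - row.onset_s, 0.0)
        elif mode == "span":
            wins[i] = (prev_onset - row.onset_s, prev_onset + 2.25 - row.onset_s)
        else:
            raise ValueError(f"unknown baseline mode {mode!r}")
        prev_onset = row.onset_s
        prev_block = row.block
    return wins


def preprocess_erp(
    recording: Recording,
    reject_uv: float = DEFAULT_REJECT_UV,
    baseline_mode: str = "gap",
) -> EpochSet:
    """ERP pipeline producing cleaned, normalized test-word epochs.

    Band-pass 0.5--20 Hz, epoch [-1.50, 3.25] s around test-word onsets,
    reject, average reference, normalize by per-epoch pooled SD, baseline
    correct using the inter-trial interval preceding each word.
    """
    rec = bandpass(recording, 0.5, 20.0)
    ev = recording.test_event_table()
    md = ev[["condition", "block", "word_index", "token", "onset_s"]].reset_index(drop=True)
    epochs = epoch(rec, ev["onset_s"].to_numpy(), -1.50, 3.25, metadata=md)
    epochs = reject_epochs(epochs, reject_uv)
    epochs = average_reference(epochs)
    epochs = normalize_epochs(epochs)
    wins = _baseline_windows(epochs.metadata, baseline_mode)
    return baseline_correct(epochs, wins)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def save_epochs(epochs: EpochSet, path) -> None:
    """Store an epoch set (data + metadata table) in an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("onsets", data=epochs.onsets)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["tmin"] = epochs.tmin
        md = f.create_group("metadata")
        for col in epochs.metadata.columns:
            values = epochs.metadata[col].to_numpy()
            if values.dtype == object:
                values = values.astype("S")
            md.create_dataset(str(col), data=values)
        md.attrs["columns"] = [str(c) for c in epochs.metadata.columns]


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        onsets = f["onsets"][()]
        rate = float(f.attrs["sampling_rate"])
        tmin = float(f.attrs["tmin"])
        cols = {}
        for col in f["metadata"].attrs["columns"]:
            v = f["metadata"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
    return EpochSet(
        data=data,
        sampling_rate=rate,
        onsets=onsets,
        metadata=pd.DataFrame(cols),
        tmin=tmin,
    )
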