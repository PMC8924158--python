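"""Minimal European Data Format (EDF) reader/writer with TSV sidecars.

Signals are stored as standard 16-bit EDF with one-second data records; the
events table and the montage travel in ``<stem>_events.tsv`` and
``<stem>_montage.tsv`` next to the signal file.  Only the subset of EDF needed
for round-tripping simulated recordings is implemented (one sampling rate for
all channels, no annotations).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MontageSpec, Recording

__all__ = ["write_recording", "read_recording", "sidecar_paths"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def sidecar_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("")
    return Path(f"{stem}_events.tsv"), Path(f"{stem}_montage.tsv")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_recording(recording: Recording, path) -> None:
    """Write an EDF file plus events and montage TSV sidecars.

    The amplitude resolution is the per-channel quantization step
    ``(phys_max - phys_min) / (dig_max - dig_min)``; the exact sample count is
    recorded in the reserved header field so reads drop record padding.
    """
    path = Path(path)
    rate = recording.sampling_rate
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    padded = np.zeros((n_ch, n_rec * spr), dtype="<i2")
    padded[:, :n_samp] = digital

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad(f"NS={n_samp}", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for ch in recording.montage.channels:
            fh.write(_pad(str(ch), 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        # records: for each record, all samples of signal 0, then signal 1, ...
        fh.write(
            np.ascontiguousarray(
                padded.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
            ).tobytes()
        )

    ev_path, mon_path = sidecar_paths(path)
    recording.events.to_csv(ev_path, sep="\t", index=False)
    mon = recording.montage.to_frame()
    with open(mon_path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rate:g}\thead_radius_cm={recording.montage.head_radius:g}\n")
        mon.to_csv(fh, sep="\t", index=False)


def read_recording(path) -> Recording:
    """Read an EDF file written by :func:`write_recording` and its sidecars."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    ev_path, mon_path = sidecar_paths(path)
    for sidecar in (ev_path, mon_path):
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar for {path.name}: expected {sidecar}")

    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode())
        rec_dur = float(head[244:252].decode())
        n_ch = int(head[252:256].decode())
        reserved = head[192:236].decode().strip()
        sig = fh.read(256 * n_ch)
        labels = [sig[16 * i : 16 * (i + 1)].decode().strip() for i in range(n_ch)]
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch

        def field(width: int, count: int, start: int) -> list[str]:
            return [
                sig[start + width * i : start + width * (i + 1)].decode().strip()
                for i in range(count)
            ]

        phys_min = np.array([float(x) for x in field(8, n_ch, off)])
        phys_max = np.array([float(x) for x in field(8, n_ch, off + 8 * n_ch)])
        dig_min = np.array([float(x) for x in field(8, n_ch, off + 16 * n_ch)])
        dig_max = np.array([float(x) for x in field(8, n_ch, off + 24 * n_ch)])
        spr = [int(x) for x in field(8, n_ch, off + 24 * n_ch + 8 * n_ch + 80 * n_ch)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates are not supported")
        spr0 = spr[0]
        raw = np.frombuffer(fh.read(2 * n_rec * n_ch * spr0), dtype="<i2")

    rate = spr0 / rec_dur
    digital = raw.reshape(n_rec, n_ch, spr0).transpose(1, 0, 2).reshape(n_ch, -1)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    n_samp = digital.shape[1]
    if reserved.startswith("NS="):
        n_samp = int(reserved[3:])
    data = data[:, :n_samp]

    with open(mon_path) as fh:
        first = fh.readline()
        meta = dict(kv.split("=") for kv in first.lstrip("# ").strip().split("\t"))
        mon_df = pd.read_csv(fh, sep="\t")
    sidecar_rate = float(meta["sampling_rate_hz"])
    if abs(sidecar_rate - rate) > 1e-6:
        raise ValueError(
            f"sampling rate mismatch: EDF header gives {rate:g} Hz, "
            f"sidecar {mon_path.name} gives {sidecar_rate:g} Hz"
        )
    montage = MontageSpec.from_frame(mon_df, head_radius=float(meta["head_radius_cm"]))
    if list(montage.channels) != labels:
        raise ValueError("channel labels in EDF and montage sidecar disagree")
    events = pd.read_csv(
        ev_path, sep="\t",
        dtype={"token": str, "condition": str, "segment_kind": str, "kind": str},
        keep_default_na=False,
    )
    return Recording(data=data, sampling_rate=rate, events=events, montage=montage)
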