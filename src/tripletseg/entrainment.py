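"""Steady-state response quantification: evoked power, ITC, SNR, DSS, learning curve.

Analysis frequencies sit on exact FFT bins by construction: 0.75 s triplets
are reshaped into 7.5 s epochs (10 triplets, 30 syllables), so the spectral
resolution is 1/7.5 Hz and the word rate (1.333... Hz) and syllable rate
(4 Hz) fall on bins 10 and 30.  No taper is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import (
    EpochSet,
    average_reference,
    normalize_epochs,
    preprocess_entrainment,
)
from .simulate import Recording

__all__ = [
    "WORD_RATE",
    "SYLLABLE_RATE",
    "SpectralResult",
    "NoiseFit",
    "SubjectExcludedError",
    "frequency_bin",
    "reshape_to_long_epochs",
    "dss_denoise",
    "evoked_power",
    "itc",
    "fit_noise_floor",
    "snr_power",
    "snr_itc",
    "spectral_analysis",
    "condition_entrainment",
    "sliding_entrainment",
    "estimate_learning_onset",
]

logger = logging.getLogger(__name__)

WORD_RATE = 4.0 / 3.0
SYLLABLE_RATE = 4.0
TARGET_RATES = (WORD_RATE, SYLLABLE_RATE)

N_ADJACENT = 6  # bins per side used for the noise estimate (0.8 Hz total span)

CONDITION_TO_KIND = {
    "RestingState": "RestingState",
    "Random": "RandomStream",
    "Structured": "StructuredStream",
}


class SubjectExcludedError(RuntimeError):
    """Raised when a subject does not meet the inclusion threshold."""


@dataclass
class SpectralResult:
    """Per-channel spectra and target-rate SNR scores."""

    frequencies: np.ndarray
    power: np.ndarray  # (channels, bins)
    itc: np.ndarray  # (channels, bins), in [0, 1]
    snr_power: dict[float, np.ndarray]  # target rate -> (channels,)
    snr_itc: dict[float, np.ndarray]
    n_trials: int

    def to_frame(self, channels=None, **extra) -> pd.DataFrame:
        n_ch = self.power.shape[0]
        if channels is None:
            channels = [f"ch{i}" for i in range(n_ch)]
        rows = []
        for f in self.snr_power:
            b = frequency_bin(self.frequencies, f)
            for c in range(n_ch):
                rows.append(
                    {
                        "channel": channels[c],
                        "frequency": f,
                        "power": self.power[c, b],
                        "itc": self.itc[c, b],
                        "snr_power": self.snr_power[f][c],
                        "snr_itc": self.snr_itc[f][c],
                        **extra,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseFit:
    """Power-law fit of the noise floor around one target bin."""

    a: float
    b: float
    residuals: np.ndarray
    adjacent_bins: np.ndarray

    def predict(self, freqs: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.log(freqs)


def frequency_bin(frequencies: np.ndarray, target: float) -> int:
    """Index of the FFT bin holding ``target`` Hz; must be an exact bin center."""
    idx = int(np.argmin(np.abs(frequencies - target)))
    step = frequencies[1] - frequencies[0]
    if abs(frequencies[idx] - target) > 1e-6 * max(1.0, target) + 1e-12:
        raise ValueError(
            f"{target} Hz is not a bin center (resolution {step:.6g} Hz); "
            "use epochs whose duration is a multiple of the target period"
        )
    return idx


def reshape_to_long_epochs(epochs: EpochSet, n_per: int = 10) -> EpochSet:
    """Concatenate consecutive retained epochs into long epochs of ``n_per``.

    Epochs are taken in chronological order; each group of ``n_per`` is
    concatenated along time, so triplet-onset phase alignment is preserved.
    Leftover epochs that do not fill a group are discarded.
    """
    n = len(epochs)
    n_groups = n // n_per
    if n_groups == 0:
        raise ValueError(f"need at least {n_per} epochs to form one long epoch, got {n}")
    order = np.argsort(epochs.onsets, kind="stable")
    data = epochs.data[order[: n_groups * n_per]]
    shape = (n_groups, n_per, epochs.n_channels, epochs.n_samples)
    long_data = (
        data.reshape(shape).transpose(0, 2, 1, 3).reshape(
            n_groups, epochs.n_channels, n_per * epochs.n_samples
        )
    )
    onsets = epochs.onsets[order][:: n_per][:n_groups]
    md = epochs.metadata.iloc[order[:: n_per][:n_groups]].reset_index(drop=True)
    md["n_short_epochs"] = n_per
    return EpochSet(
        data=long_data,
        sampling_rate=epochs.sampling_rate,
        onsets=onsets,
        metadata=md,
        tmin=0.0,
    )


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------


def dss_denoise(epochs: EpochSet, n_pca: int = 30, n_dss: int = 6) -> EpochSet:
    """Denoising source separation with trial averaging as the bias function.

    A first PCA on the total covariance keeps ``n_pca`` whitened components; a
    second PCA on the covariance of the trial average in whitened space keeps
    ``n_dss`` components.  Data are projected onto the retained components and
    back to channel space, preserving channel units.
    """
    n_ch = epochs.n_channels
    n_pca = min(n_pca, n_ch)
    if n_dss > n_pca:
        raise ValueError("n_dss cannot exceed n_pca")
    X = epochs.data  # (trials, ch, samples)
    c0 = np.einsum("tcs,tds->cd", X, X) / (X.shape[0] * X.shape[2])
    evals, evecs = np.linalg.eigh(c0)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    pos = evals > evals[0] * 1e-12
    if pos[:n_pca].sum() < n_pca:
        raise ValueError(
            f"covariance rank {int(pos.sum())} below n_pca={n_pca}; reduce n_pca"
        )
    v = evecs[:, :n_pca]
    lam = evals[:n_pca]
    whiten = v / np.sqrt(lam)  # (ch, p): y = whiten.T @ x
    color = v * np.sqrt(lam)  # (ch, p): x = color @ y

    avg = X.mean(axis=0)  # (ch, samples)
    y = whiten.T @ avg
    c1 = y @ y.T / y.shape[1]
    d_evals, d_evecs = np.linalg.eigh(c1)
    q = d_evecs[:, ::-1][:, :n_dss]

    transform = color @ q @ q.T @ whiten.T  # (ch, ch)
    out = np.einsum("cd,tds->tcs", transform, X)
    return replace(epochs, data=out)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _spectra(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.sampling_rate)
    spec = np.fft.rfft(epochs.data, axis=-1)
    return freqs, spec


def evoked_power(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the trial-averaged response.

    Returns ``(frequencies, power)`` with power of shape (channels, bins),
    computed as |FFT(mean over trials)|^2.
    """
    if len(epochs) < 1:
        raise ValueError("need at least one trial")
    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.sampling_rate)
    spec = np.fft.rfft(epochs.data.mean(axis=0), axis=-1)
    return freqs, np.abs(spec) ** 2


def itc(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Inter-trial coherence: modulus of the mean unit phasor across trials."""
    if len(epochs) < 2:
        raise ValueError("ITC requires at least two trials")
    freqs, spec = _spectra(epochs)
    mag = np.abs(spec)
    phasors = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    return freqs, np.abs(phasors.mean(axis=0))


def _adjacent_bins(frequencies: np.ndarray, target: float) -> tuple[int, np.ndarray]:
    t = frequency_bin(frequencies, target)
    if t - N_ADJACENT < 0 or t + N_ADJACENT >= len(frequencies):
        raise ValueError(
            f"need {N_ADJACENT} bins on each side of {target} Hz within the spectrum"
        )
    adj = np.r_[t - N_ADJACENT : t, t + 1 : t + 1 + N_ADJACENT]
    return t, adj


def fit_noise_floor(power_ch: np.ndarray, frequencies: np.ndarray, target: float) -> NoiseFit:
    """Power-law fit log(P) = a + b log(f) on the 12 bins adjacent to ``target``."""
    t, adj = _adjacent_bins(frequencies, target)
    p = power_ch[adj]
    if np.any(p <= 0):
        raise ValueError("nonpositive power in noise-fit bins; add a noise floor")
    x = np.log(frequencies[adj])
    ylog = np.log(p)
    b, a = np.polyfit(x, ylog, 1)
    fit = NoiseFit(a=float(a), b=float(b), residuals=ylog - (a + b * x), adjacent_bins=adj)
    return fit


def snr_power(power: np.ndarray, frequencies: np.ndarray, target: float) -> np.ndarray:
    """Z-like score of target-bin log-power against the power-law noise floor.

    For each channel the 12 adjacent bins (target excluded) are fit with
    log(P) = a + b*log(f); the score is the target bin's log-residual
    standardized by the mean and SD of the fit-bin residuals.
    """
    power = np.atleast_2d(power)
    t, adj = _adjacent_bins(frequencies, target)
    out = np.empty(power.shape[0])
    for c in range(power.shape[0]):
        nf = fit_noise_floor(power[c], frequencies, target)
        if power[c, t] <= 0:
            raise ValueError("nonpositive power at target bin")
        resid_t = np.log(power[c, t]) - nf.predict(np.array([target]))[0]
        # unbiased residual SD for a 2-parameter fit
        sd = np.sqrt((nf.residuals**2).sum() / (len(adj) - 2))
        centred = resid_t - nf.residuals.mean()
        # an exactly power-law spectrum has zero residuals everywhere: score 0
        tol = 1e-9 * max(1.0, np.abs(np.log(power[c, adj])).max())
        if sd < tol:
            out[c] = 0.0 if abs(centred) < tol else np.sign(centred) * np.inf
        else:
            out[c] = centred / sd
    return out


def snr_itc(itc_vals: np.ndarray, frequencies: np.ndarray, target: float) -> np.ndarray:
    """Z-score of the target-bin ITC against the 12 adjacent bins."""
    itc_vals = np.atleast_2d(itc_vals)
    t, adj = _adjacent_bins(frequencies, target)
    noise = itc_vals[:, adj]
    sd = noise.std(axis=1, ddof=1)
    centred = itc_vals[:, t] - noise.mean(axis=1)
    degenerate = sd < 1e-12
    if np.any(degenerate & (np.abs(centred) >= 1e-12)):
        raise ValueError("zero ITC variance across adjacent bins")
    out = np.zeros_like(centred)
    ok = ~degenerate
    out[ok] = centred[ok] / sd[ok]
    return out


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------


def spectral_analysis(
    long_epochs: EpochSet,
    targets: tuple[float, ...] = TARGET_RATES,
    use_dss: bool = True,
    n_pca: int = 30,
    n_dss: int = 6,
) -> SpectralResult:
    """Reference, normalize, optionally DSS-denoise, then power/ITC/SNR."""
    ep = normalize_epochs(average_reference(long_epochs))
    if use_dss:
        # average referencing reduces the rank by one
        n_pca = min(n_pca, ep.n_channels - 1)
        ep = dss_denoise(ep, n_pca=n_pca, n_dss=min(n_dss, n_pca))
    freqs, pw = evoked_power(ep)
    _, coh = itc(ep)
    snr_p = {f: snr_power(pw, freqs, f) for f in targets}
    snr_i = {f: snr_itc(coh, freqs, f) for f in targets}
    return SpectralResult(
        frequencies=freqs, power=pw, itc=coh, snr_power=snr_p, snr_itc=snr_i,
        n_trials=len(ep),
    )


def condition_entrainment(
    recording: Recording,
    condition: str,
    min_segments: int = 6,
    use_dss: bool = True,
    n_pca: int = 30,
    n_dss: int = 6,
    epochs: EpochSet | None = None,
) -> SpectralResult:
    """Entrainment spectra for one condition of one recording.

    ``condition`` is one of RestingState, Random, Structured; structured pools
    the long stream and the eight short streams.  Pass precomputed ``epochs``
    (the output of :func:`preprocess_entrainment`) to avoid re-filtering when
    analysing several conditions.  Raises :class:`SubjectExcludedError` when
    fewer than ``min_segments`` clean 0.75 s segments are available.
    """
    if condition not in CONDITION_TO_KIND:
        raise ValueError(f"unknown condition {condition!r}; use {sorted(CONDITION_TO_KIND)}")
    if epochs is None:
        epochs = preprocess_entrainment(recording)
    sel = epochs.select(
        (epochs.metadata["segment_kind"] == CONDITION_TO_KIND[condition]).to_numpy()
    )
    if len(sel) < min_segments:
        raise SubjectExcludedError(
            f"only {len(sel)} clean segments for condition {condition} "
            f"(minimum {min_segments})"
        )
    long_ep = reshape_to_long_epochs(sel, 10)
    return spectral_analysis(long_ep, use_dss=use_dss, n_pca=n_pca, n_dss=n_dss)


def sliding_entrainment(
    recording: Recording,
    window_s: float = 120.0,
    step_s: float = 1.5,
    use_dss: bool = True,
    n_pca: int = 30,
    n_dss: int = 6,
    epochs: EpochSet | None = None,
) -> pd.DataFrame:
    """Sliding-window entrainment over the concatenated session.

    Retained 0.75 s epochs from all phases (test blocks excluded) are
    concatenated chronologically; each window of ``window_s`` seconds (160
    epochs for 2 min) is reshaped into 7.5 s epochs and analysed like a
    condition.  Windows are labeled by their center time on the concatenated
    timeline (first 2 min window -> 60 s).  Windows with fewer than 10 epochs
    are skipped with a log message.

    Returns a long table: window_center, channel, frequency, power, itc,
    snr_power, snr_itc.
    """
    if epochs is None:
        epochs = preprocess_entrainment(recording)
    order = np.argsort(epochs.onsets, kind="stable")
    ep = epochs.select(order)
    epoch_len = ep.n_samples / ep.sampling_rate
    per_window = int(round(window_s / epoch_len))
    step = max(int(round(step_s / epoch_len)), 1)
    frames = []
    starts = range(0, len(ep) - per_window + 1, step)
    for i0 in starts:
        n_long = per_window // 10
        if n_long < 1:
            logger.info("window at epoch %d shorter than one long epoch; skipped", i0)
            continue
        window = ep.select(np.arange(i0, i0 + per_window))
        long_ep = reshape_to_long_epochs(window, 10)
        res = spectral_analysis(long_ep, use_dss=use_dss, n_pca=n_pca, n_dss=n_dss)
        center = (i0 + per_window / 2) * epoch_len
        frames.append(res.to_frame(window_center=center))
    if not frames:
        raise ValueError("no full window fits in the recording")
    return pd.concat(frames, ignore_index=True)


def estimate_learning_onset(curve: pd.DataFrame, frequency: float = WORD_RATE,
                            measure: str = "power", window_s: float = 120.0,
                            resolution_s: float = 0.1) -> float:
    """Estimate the learning onset time from a sliding-window curve.

    The channel-mean amplitude (sqrt of evoked power, or ITC) at the target
    bin is floor-corrected in quadrature (the measurable quantity is
    sqrt(signal^2 + noise^2)), normalized by its plateau (mean of the top
    decile), and fit by least squares with the ramp a sliding window of
    ``window_s`` seconds produces for a sharp onset at T:
    ``clip((center - T)/window_s + 1/2, 0, 1)``.  Returns the best-fitting T
    on the concatenated-session timeline.
    """
    sub = curve[np.isclose(curve["frequency"], frequency)]
    g = sub.groupby("window_center")
    y = np.sqrt(g["power"].mean()) if measure == "power" else g["itc"].mean()
    centers = y.index.to_numpy(float)
    raw = y.to_numpy(float)
    k = max(len(raw) // 10, 2)
    floor = np.median(raw[:k])
    vals = np.sqrt(np.maximum(raw**2 - floor**2, 0.0))
    hi = np.mean(np.sort(vals)[-k:])
    if hi <= 0:
        raise ValueError("flat curve; no onset detectable")
    v = vals / hi
    candidates = np.arange(centers[0], centers[-1], resolution_s)
    ramps = np.clip((centers[None, :] - candidates[:, None]) / window_s + 0.5, 0.0, 1.0)
    ss = ((v[None, :] - ramps) ** 2).sum(axis=1)
    return float(candidates[np.argmin(ss)])
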