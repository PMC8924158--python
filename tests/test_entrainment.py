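import cmath
import math

import numpy as np
import pandas as pd
import pytest

from tripletseg import entrainment as ent
from tripletseg import group_stats as gs
from tripletseg.preprocess import EpochSet, preprocess_entrainment
from tripletseg.simulate import SimulationConfig, make_montage, simulate_recording
from tripletseg.stimuli import Segment, SessionSchedule, build_lexicon, generate_random_stream, generate_structured_stream


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the numpy FFT path
# ---------------------------------------------------------------------------


def dft_bin(x, k):
    """Naive DFT coefficient at bin k."""
    n = len(x)
    return sum(x[j] * cmath.exp(-2j * math.pi * k * j / n) for j in range(n))


def oracle_evoked_power(data):
    """|DFT(mean over trials)|^2, computed with explicit loops."""
    mean = data.mean(axis=0)
    n_ch, n = mean.shape
    n_bins = n // 2 + 1
    out = np.empty((n_ch, n_bins))
    for c in range(n_ch):
        for k in range(n_bins):
            out[c, k] = abs(dft_bin(mean[c], k)) ** 2
    return out


def oracle_itc(data):
    n_tr, n_ch, n = data.shape
    n_bins = n // 2 + 1
    out = np.empty((n_ch, n_bins))
    for c in range(n_ch):
        for k in range(n_bins):
            acc = 0.0 + 0.0j
            for t in range(n_tr):
                z = dft_bin(data[t, c], k)
                acc += z / abs(z) if abs(z) > 0 else 0.0
            out[c, k] = abs(acc) / n_tr
    return out


class TestOracleEquivalence:
    def test_power_and_itc_match_brute_force(self, epoch_factory):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(8, 3, 24))
        ep = epoch_factory(data, rate=24.0)
        _, pw = ent.evoked_power(ep)
        _, coh = ent.itc(ep)
        assert np.allclose(pw, oracle_evoked_power(data), atol=1e-10, rtol=1e-10)
        assert np.allclose(coh, oracle_itc(data), atol=1e-10, rtol=1e-10)


class TestReshape:
    def test_240_to_24(self, epoch_factory):
        ep = epoch_factory(np.zeros((240, 2, 225)), rate=300.0)
        long = ent.reshape_to_long_epochs(ep, 10)
        assert len(long) == 24
        assert long.n_samples == 2250

    def test_leftover_discarded(self, epoch_factory):
        ep = epoch_factory(np.zeros((25, 2, 225)), rate=300.0)
        assert len(ent.reshape_to_long_epochs(ep, 10)) == 2

    def test_too_few_errors(self, epoch_factory):
        ep = epoch_factory(np.zeros((7, 2, 225)), rate=300.0)
        with pytest.raises(ValueError):
            ent.reshape_to_long_epochs(ep, 10)

    def test_sinusoid_lands_on_bin_10(self, epoch_factory):
        # 1.333... Hz spans exactly one cycle per 0.75 s epoch
        t = np.arange(225) / 300.0
        short = np.sin(2 * np.pi * ent.WORD_RATE * t)
        ep = epoch_factory(np.tile(short, (30, 1, 1)), rate=300.0)
        long = ent.reshape_to_long_epochs(ep, 10)
        freqs, pw = ent.evoked_power(long)
        assert np.argmax(pw[0]) == 10
        assert ent.frequency_bin(freqs, ent.WORD_RATE) == 10
        assert ent.frequency_bin(freqs, ent.SYLLABLE_RATE) == 30
        assert pw[0, 10] / pw[0].sum() > 0.99

    def test_chronological_order(self, epoch_factory):
        data = np.arange(40, dtype=float).reshape(40, 1, 1) * np.ones((40, 1, 225))
        md = pd.DataFrame(index=range(40))
        ep = EpochSet(data=data, sampling_rate=300.0, onsets=np.arange(40) * 0.75,
                      metadata=md)
        long = ent.reshape_to_long_epochs(ep, 10)
        assert long.data[0, 0, 0] == 0.0
        assert long.data[3, 0, 0] == 30.0


class TestITCProperties:
    def test_identical_trials_itc_one(self, epoch_factory):
        rng = np.random.default_rng(0)
        trial = rng.normal(size=(2, 128))
        ep = epoch_factory(np.tile(trial, (12, 1, 1)), rate=128.0)
        _, coh = ent.itc(ep)
        nonzero = np.abs(np.fft.rfft(trial, axis=-1)) > 1e-9
        assert np.allclose(coh[nonzero], 1.0)

    def test_uniform_phases_vanish(self, epoch_factory):
        n_tr = 64
        t = np.arange(128) / 128.0
        phases = 2 * np.pi * np.arange(n_tr) / n_tr
        data = np.stack([np.sin(2 * np.pi * 8 * t + p)[None, :] for p in phases])
        ep = epoch_factory(data, rate=128.0)
        _, coh = ent.itc(ep)
        assert coh[0, 8] < 1e-10

    def test_random_phase_expectation(self, epoch_factory):
        """E[ITC] for N random phases ~ sqrt(pi)/(2 sqrt(N)) (Rayleigh resultant)."""
        rng = np.random.default_rng(1)
        n_tr = 16
        vals = []
        t = np.arange(64) / 64.0
        for _ in range(300):
            ph = rng.uniform(0, 2 * np.pi, n_tr)
            data = np.stack([np.sin(2 * np.pi * 4 * t + p)[None, :] for p in ph])
            _, coh = ent.itc(epoch_factory(data, rate=64.0))
            vals.append(coh[0, 4])
        expected = math.sqrt(math.pi) / (2 * math.sqrt(n_tr))
        assert abs(np.mean(vals) - expected) < 0.02

    def test_bounds(self, epoch_factory):
        rng = np.random.default_rng(2)
        ep = epoch_factory(rng.normal(size=(9, 4, 50)), rate=50.0)
        _, coh = ent.itc(ep)
        assert np.all(coh >= 0) and np.all(coh <= 1 + 1e-12)


class TestEvokedPower:
    def test_single_cosine_all_power_at_bin(self, epoch_factory):
        t = np.arange(75) / 100.0
        ep = epoch_factory(np.cos(2 * np.pi * 4 * t)[None, None, :], rate=100.0)
        freqs, pw = ent.evoked_power(ep)
        b = ent.frequency_bin(freqs, 4.0)
        assert pw[0, b] / pw.sum() > 0.999

    def test_antiphase_trials_cancel(self, epoch_factory):
        t = np.arange(75) / 100.0
        x = np.sin(2 * np.pi * 4 * t)
        ep = epoch_factory(np.stack([x[None, :], -x[None, :]]), rate=100.0)
        freqs, pw = ent.evoked_power(ep)
        assert pw[0, ent.frequency_bin(freqs, 4.0)] < 1e-20

    def test_random_phases_converge_to_zero(self, epoch_factory):
        rng = np.random.default_rng(3)
        t = np.arange(75) / 100.0
        n_tr = 400
        data = np.stack(
            [np.sin(2 * np.pi * 4 * t + rng.uniform(0, 2 * np.pi))[None, :] for _ in range(n_tr)]
        )
        freqs, pw = ent.evoked_power(epoch_factory(data, rate=100.0))
        b = ent.frequency_bin(freqs, 4.0)
        single = np.abs(np.fft.rfft(data[0, 0]))[b] ** 2
        assert pw[0, b] < 0.05 * single


class TestSNR:
    def freqs(self):
        return np.fft.rfftfreq(2250, 1 / 300.0)

    def test_power_law_scores_zero(self):
        f = self.freqs()
        p = np.zeros(len(f))
        p[1:] = 7.3 * f[1:] ** -1.2
        assert ent.snr_power(p, f, 4.0)[0] == 0.0

    def test_boosted_target_positive(self):
        rng = np.random.default_rng(4)
        f = self.freqs()
        p = np.zeros(len(f))
        p[1:] = f[1:] ** -1.0 * np.exp(rng.normal(0, 0.1, len(f) - 1))
        base = ent.snr_power(p, f, ent.WORD_RATE)[0]
        p2 = p.copy()
        p2[ent.frequency_bin(f, ent.WORD_RATE)] *= 10
        assert ent.snr_power(p2, f, ent.WORD_RATE)[0] > max(base, 3.0)

    def test_flat_itc_zero_score(self):
        f = self.freqs()
        itc_vals = np.full(len(f), 0.3)
        assert ent.snr_itc(itc_vals, f, 4.0)[0] == 0.0

    def test_zero_variance_with_peak_errors(self):
        f = self.freqs()
        itc_vals = np.full(len(f), 0.3)
        itc_vals[ent.frequency_bin(f, 4.0)] = 1.0
        with pytest.raises(ValueError, match="variance"):
            ent.snr_itc(itc_vals, f, 4.0)

    def test_itc_z_formula(self):
        """Hand-computed z over the 12 adjacent bins."""
        f = self.freqs()
        itc_vals = np.full(len(f), 0.1)
        b = ent.frequency_bin(f, 4.0)
        adj = np.r_[b - 6 : b, b + 1 : b + 7]
        noise = 0.1 + 0.01 * np.arange(12)
        itc_vals[adj] = noise
        itc_vals[b] = 0.9
        expected = (0.9 - noise.mean()) / noise.std(ddof=1)
        assert ent.snr_itc(itc_vals, f, 4.0)[0] == pytest.approx(expected)

    def test_delta_itc_large_positive(self):
        f = self.freqs()
        rng = np.random.default_rng(5)
        itc_vals = np.abs(rng.normal(0, 0.02, len(f)))
        b = ent.frequency_bin(f, ent.WORD_RATE)
        itc_vals[b] = 1.0
        assert ent.snr_itc(itc_vals, f, ent.WORD_RATE)[0] > math.sqrt(12) - 1

    def test_nonpositive_power_errors(self):
        f = self.freqs()
        p = np.zeros(len(f))
        with pytest.raises(ValueError, match="noise floor|nonpositive"):
            ent.snr_power(p, f, 4.0)

    def test_needs_six_bins_each_side(self):
        f = self.freqs()
        p = np.ones(len(f))
        with pytest.raises(ValueError):
            ent.snr_power(p, f, f[3])

    def test_white_noise_null_calibration(self, epoch_factory):
        """Scores on signal-free spectra: mean ~ 0, SD ~ 1 (+-0.3)."""
        rng = np.random.default_rng(6)
        scores = []
        for _ in range(300):
            data = rng.normal(size=(12, 4, 450))
            ep = epoch_factory(data, rate=60.0)
            freqs, pw = ent.evoked_power(ep)
            scores.extend(ent.snr_power(pw, freqs, 4.0))
        scores = np.asarray(scores)
        assert abs(scores.mean()) < 0.3
        assert abs(scores.std() - 1.0) < 0.3


class TestDSS:
    def test_identity_on_noiseless_identical_trials(self, epoch_factory):
        rng = np.random.default_rng(7)
        topo = rng.normal(size=(8, 3))
        src = rng.normal(size=(3, 500))
        data = np.tile(topo @ src, (10, 1, 1))
        out = ent.dss_denoise(epoch_factory(data, rate=100.0), n_pca=3, n_dss=3)
        assert np.allclose(out.data, data, atol=1e-9)

    def test_pure_noise_power_reduced(self, epoch_factory):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(30, 10, 400))
        ep = epoch_factory(data, rate=100.0)
        out = ent.dss_denoise(ep, n_pca=10, n_dss=2)
        _, p_in = ent.evoked_power(ep)
        _, p_out = ent.evoked_power(out)
        assert p_out.sum() <= p_in.sum()

    def test_snr_improves_with_dss(self, epoch_factory):
        rng = np.random.default_rng(9)
        t = np.arange(750) / 100.0
        sig = np.sin(2 * np.pi * 4 * t)
        topo = rng.normal(size=12)
        wins = 0
        for rep in range(10):
            noise = rng.normal(scale=6.0, size=(20, 12, 750))
            data = noise + 0.5 * topo[None, :, None] * sig
            ep = epoch_factory(data, rate=100.0)
            freqs, p_raw = ent.evoked_power(ep)
            p_dss = ent.evoked_power(ent.dss_denoise(ep, n_pca=12, n_dss=2))[1]
            raw = ent.snr_power(p_raw, freqs, 4.0).mean()
            den = ent.snr_power(p_dss, freqs, 4.0).mean()
            wins += den > raw
        assert wins >= 8

    def test_rank_deficient_errors(self, epoch_factory):
        data = np.tile(np.ones((1, 400)), (5, 8, 1))  # rank 1
        with pytest.raises(ValueError, match="n_pca"):
            ent.dss_denoise(epoch_factory(data, rate=100.0), n_pca=8, n_dss=2)

    def test_trial_count_unchanged(self, epoch_factory):
        rng = np.random.default_rng(10)
        ep = epoch_factory(rng.normal(size=(14, 8, 300)), rate=100.0)
        assert len(ent.dss_denoise(ep, n_pca=8, n_dss=4)) == 14


class TestConditionChain:
    def test_resting_not_entrained(self, recording):
        res = ent.condition_entrainment(recording, "RestingState")
        assert res.snr_power[ent.SYLLABLE_RATE].mean() < 2.0
        assert res.snr_power[ent.WORD_RATE].mean() < 2.0

    def test_random_syllable_only(self, recording):
        res = ent.condition_entrainment(recording, "Random")
        assert res.snr_itc[ent.SYLLABLE_RATE].mean() > 2.0
        assert res.snr_itc[ent.WORD_RATE].mean() < 2.0

    def test_structured_both_rates(self, recording):
        res = ent.condition_entrainment(recording, "Structured")
        assert res.snr_itc[ent.SYLLABLE_RATE].mean() > 2.0
        assert res.snr_itc[ent.WORD_RATE].mean() > 2.0

    def test_unknown_condition(self, recording):
        with pytest.raises(ValueError):
            ent.condition_entrainment(recording, "Bogus")

    def test_exclusion_below_min_segments(self, recording):
        with pytest.raises(ent.SubjectExcludedError):
            ent.condition_entrainment(recording, "RestingState", min_segments=10_000)

    def test_itc_in_bounds(self, recording):
        res = ent.condition_entrainment(recording, "Structured")
        assert np.all(res.itc >= 0) and np.all(res.itc <= 1 + 1e-12)


def mini_schedule(lexicon, structured_s=360.0, seed=0):
    """RS + random + one long structured stream (for learning-curve tests)."""
    segs = []
    t = 0.0
    for kind, dur, payload in [
        ("RestingState", 60.0, None),
        ("RandomStream", 120.0, generate_random_stream(lexicon, 120.0, seed)),
        ("StructuredStream", structured_s,
         generate_structured_stream(lexicon, structured_s, seed + 1)),
    ]:
        segs.append(Segment(kind, t, dur, payload))
        t += dur
    return SessionSchedule(lexicon=lexicon, segments=tuple(segs), seed=seed)


@pytest.fixture(scope="module")
def learning_recording(lexicon):
    # a constant strong syllable response dominates the per-epoch SD, so
    # normalization does not compress the gated word-rate component
    sch = mini_schedule(lexicon, structured_s=360.0, seed=3)
    cfg = SimulationConfig(
        seed=21, syllable_amplitude=14.0, word_rate_amplitude=3.0,
        learning_onset_s=120.0, learning_ramp_s=10.0,
        pink_scale=0.5, white_scale=0.5,
    )
    montage = make_montage(16, head_radius=10.5 * np.sqrt(16 / 128), seed=0)
    return simulate_recording(sch, montage, cfg)


class TestSliding:
    def test_first_window_center_60s(self, recording):
        curve = ent.sliding_entrainment(recording, use_dss=False)
        assert curve["window_center"].min() == pytest.approx(60.0)

    def test_syllable_rate_stationary(self, learning_recording):
        curve = ent.sliding_entrainment(learning_recording, use_dss=False)
        syl = curve[np.isclose(curve["frequency"], ent.SYLLABLE_RATE)]
        g = syl.groupby("window_center")["snr_itc"].mean()
        # all windows overlapping the streams show the syllable response
        assert (g[g.index > 120] > 2.0).mean() > 0.95

    def test_learning_onset_recovered(self, learning_recording):
        curve = ent.sliding_entrainment(learning_recording, use_dss=False)
        est = ent.estimate_learning_onset(curve)
        # structured stream starts at 180 s; configured onset 120 s after that
        assert abs(est - 300.0) <= 1.5

    def test_word_rate_silent_before_onset(self, learning_recording):
        curve = ent.sliding_entrainment(learning_recording, use_dss=False)
        word = curve[np.isclose(curve["frequency"], ent.WORD_RATE)]
        g = word.groupby("window_center")["snr_power"].mean()
        early = g[g.index <= 180.0]
        late = g[g.index >= 330.0]
        assert early.max() < 2.0
        assert late.min() > 3.0


class TestAmplitudeMonotonicity:
    def test_word_snr_monotone_in_amplitude(self, lexicon):
        from scipy.stats import spearmanr

        montage = make_montage(8, head_radius=10.5 * np.sqrt(8 / 128), seed=0)
        sch = mini_schedule(lexicon, structured_s=180.0, seed=5)
        amps, snrs = [], []
        for amp in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = SimulationConfig(seed=33, word_rate_amplitude=amp,
                                   learning_onset_s=0.0, learning_ramp_s=0.001,
                                   pink_scale=8.0, white_scale=2.0)
            rec = simulate_recording(sch, montage, cfg)
            res = ent.condition_entrainment(rec, "Structured")
            amps.append(amp)
            snrs.append(res.snr_power[ent.WORD_RATE].mean())
        rho = spearmanr(amps, snrs).statistic
        assert rho > 0.9
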