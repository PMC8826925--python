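"""Spectral estimator: windowed FFT spectra, band integration, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sleepqeeg.hypnogram import Hypnogram
from sleepqeeg.edf_io import EegRecording
from sleepqeeg.spectral import (
    BandDefinition,
    SEGMENTS_PER_EPOCH,
    SegmentSpectrum,
    band_power,
    compute_segment_spectrum,
    default_bands,
    epoch_band_powers,
    participant_summary,
)

FS = 125.0
SEG_N = 625


def oracle_segment_power(segment, fs=FS):
    """Direct-DFT (matrix, no FFT) one-sided power spectrum oracle."""
    x = np.asarray(segment, dtype=float)
    n = x.size
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    xw = (x - x.mean()) * w
    k = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n) @ xw
    p = np.abs(dft) ** 2 / (n * np.sum(w ** 2))
    if n % 2 == 0:
        p[1:-1] *= 2
    else:
        p[1:] *= 2
    return k * fs / n, p


def test_zero_segment_gives_zero_spectrum():
    spec = compute_segment_spectrum(np.zeros(SEG_N), FS)
    assert np.all(spec.power == 0.0)


def test_frequency_grid_is_0p2_hz():
    spec = compute_segment_spectrum(np.random.default_rng(0).normal(size=SEG_N), FS)
    assert spec.freqs[0] == 0.0
    assert np.allclose(np.diff(spec.freqs), 0.2)
    assert len(spec.freqs) == SEG_N // 2 + 1


def test_wrong_segment_length_rejected():
    with pytest.raises(ValueError, match="625"):
        compute_segment_spectrum(np.zeros(624), FS)


def test_unit_sinusoid_total_power_is_half():
    t = np.arange(SEG_N) / FS
    spec = compute_segment_spectrum(np.sin(2 * np.pi * 10.0 * t), FS)
    total = spec.power.sum()
    assert total == pytest.approx(0.5, rel=1e-9)
    # concentrated at/adjacent to the 10 Hz bin
    k10 = int(round(10.0 / 0.2))
    assert spec.power[k10 - 2:k10 + 3].sum() / total > 0.999


def test_matches_direct_dft_oracle(rng):
    seg = rng.normal(size=SEG_N)
    spec = compute_segment_spectrum(seg, FS)
    freqs, p = oracle_segment_power(seg)
    assert np.allclose(spec.freqs, freqs)
    assert np.allclose(spec.power, p, rtol=1e-9, atol=1e-15)


def test_white_noise_parseval_calibration(rng):
    """Total one-sided power estimates the variance (unbiased, within 3 SE)."""
    sigma2 = 4.0
    n_seg = 1200
    totals = np.empty(n_seg)
    for i in range(n_seg):
        seg = rng.normal(0.0, np.sqrt(sigma2), size=SEG_N)
        totals[i] = compute_segment_spectrum(seg, FS).power.sum()
    se = totals.std(ddof=1) / np.sqrt(n_seg)
    assert abs(totals.mean() - sigma2) < 3 * se


@given(st.floats(min_value=0.1, max_value=50.0))
def test_scaling_signal_scales_power_quadratically(c):
    seg = np.sin(2 * np.pi * 7.3 * np.arange(SEG_N) / FS) + 0.5
    base = compute_segment_spectrum(seg, FS).power
    scaled = compute_segment_spectrum(c * seg, FS).power
    assert np.allclose(scaled, c ** 2 * base, rtol=1e-9, atol=1e-12)


class TestBandPower:
    def test_bin_below_min_freq_excluded_everywhere(self):
        freqs = np.arange(SEG_N // 2 + 1) * 0.2
        power = np.zeros_like(freqs)
        power[3] = 5.0            # 0.6 Hz bin
        spec = SegmentSpectrum(freqs=freqs, power=power)
        for band in default_bands():
            assert band_power(spec, band) == 0.0
        assert band_power(spec, BandDefinition("all", 0.8, 20.0)) == 0.0

    def test_shared_edge_goes_to_upper_band(self):
        freqs = np.arange(SEG_N // 2 + 1) * 0.2
        power = np.zeros_like(freqs)
        power[int(round(4.0 / 0.2))] = 1.0       # exactly 4.0 Hz
        spec = SegmentSpectrum(freqs=freqs, power=power)
        delta, theta = default_bands()[0], default_bands()[1]
        assert band_power(spec, delta) == 0.0
        assert band_power(spec, theta) == 1.0

    def test_unit_spectrum_counts_qualifying_bins(self):
        freqs = np.arange(SEG_N // 2 + 1) * 0.2
        spec = SegmentSpectrum(freqs=freqs, power=np.ones_like(freqs))
        # delta [1, 4): bins 1.0, 1.2, ..., 3.8
        assert band_power(spec, default_bands()[0]) == 15.0

    def test_band_additivity(self, rng):
        seg = rng.normal(size=SEG_N)
        spec = compute_segment_spectrum(seg, FS)
        total = band_power(spec, BandDefinition("wide", 1.0, 20.0), min_freq=0.8)
        parts = sum(band_power(spec, b, min_freq=0.8) for b in default_bands())
        assert parts == pytest.approx(total, rel=1e-12)


class TestEpochBandPowers:
    def test_six_segment_arithmetic_mean(self):
        """Segments with band powers 1..6 uV^2 average to 3.5."""
        t = np.arange(SEG_N) / FS
        segs = [np.sqrt(2.0 * k) * np.sin(2 * np.pi * 10.0 * t)
                for k in range(1, 7)]       # each has total power k
        epoch = np.tile(np.concatenate(segs), (2, 1))
        ep = epoch_band_powers(epoch, "N2", sampling_rate=FS)
        assert ep.band_power["alpha"] == pytest.approx(3.5, rel=1e-6)

    def test_channels_averaged_at_band_power_level(self):
        t = np.arange(SEGMENTS_PER_EPOCH * SEG_N) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        epoch = np.stack([2.0 * tone, np.sqrt(8.0) * tone])  # powers 2 and 4
        ep = epoch_band_powers(epoch, "N2", sampling_rate=FS)
        assert ep.band_power["alpha"] == pytest.approx(3.0, rel=1e-6)

    def test_13hz_tone_lands_in_sigma(self):
        t = np.arange(SEGMENTS_PER_EPOCH * SEG_N) / FS
        epoch = np.tile(np.sin(2 * np.pi * 13.0 * t), (2, 1))
        ep = epoch_band_powers(epoch, "N2", sampling_rate=FS)
        total = sum(ep.band_power.values())
        assert ep.band_power["sigma"] / total > 0.99
        assert ep.band_power["alpha"] / total < 0.01
        assert ep.band_power["beta"] / total < 0.01

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            epoch_band_powers(np.zeros((2, 6 * SEG_N)), "REMISH", sampling_rate=FS)

    def test_epoch_must_hold_exactly_six_segments(self):
        with pytest.raises(ValueError, match="6"):
            epoch_band_powers(np.zeros((2, 5 * SEG_N)), "N2", sampling_rate=FS)

    def test_oracle_agreement_on_random_epochs(self, rng):
        """Band powers match the direct-DFT oracle within 1e-9 relative."""
        n = 6 * SEG_N
        dftmat = np.exp(-2j * np.pi * np.outer(
            np.arange(SEG_N // 2 + 1), np.arange(SEG_N)) / SEG_N)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(SEG_N) / SEG_N))
        freqs = np.arange(SEG_N // 2 + 1) * FS / SEG_N

        def oracle_epoch(epoch):
            out = {b.name: 0.0 for b in default_bands()}
            for ch in range(2):
                for s in range(6):
                    seg = epoch[ch, s * SEG_N:(s + 1) * SEG_N]
                    xw = (seg - seg.mean()) * w
                    p = np.abs(dftmat @ xw) ** 2 / (SEG_N * np.sum(w ** 2))
                    p[1:] *= 2
                    for b in default_bands():
                        m = (freqs >= b.lo) & (freqs < b.hi) & (freqs >= 0.8)
                        out[b.name] += p[m].sum()
            return {k: v / 12.0 for k, v in out.items()}

        for _ in range(100):
            epoch = rng.normal(size=(2, n))
            got = epoch_band_powers(epoch, "N2", sampling_rate=FS).band_power
            want = oracle_epoch(epoch)
            for band in want:
                assert got[band] == pytest.approx(want[band], rel=1e-9)


class TestParticipantSummary:
    @staticmethod
    def _recording(signal_by_epoch, fs=FS):
        sig = np.concatenate(signal_by_epoch)
        return EegRecording(channels=[("C3-A2", sig), ("C4-A1", sig.copy())],
                            sampling_rate=fs)

    def test_identical_epochs_give_log_of_single_value(self):
        t = np.arange(6 * SEG_N) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)        # alpha power 0.5
        rec = self._recording([tone] * 4)
        hyp = Hypnogram(("N2", "N2", "R", "N2"))
        s = participant_summary(rec, hyp)
        assert s.log_power["total"]["alpha"] == pytest.approx(np.log10(0.5), abs=1e-6)

    def test_epoch_count_conservation(self, rng):
        n_epochs = 15
        sig = rng.normal(size=6 * SEG_N * n_epochs)
        rec = EegRecording(channels=[("C3-A2", sig), ("C4-A1", sig.copy())],
                           sampling_rate=FS)
        hyp = Hypnogram(tuple(["N2"] * 10 + ["R"] * 5))
        s = participant_summary(rec, hyp)
        assert s.epoch_counts == {"total": 15, "nrem": 10, "rem": 5}

    def test_wake_epochs_excluded_and_absent_states_flagged(self, rng):
        sig = rng.normal(size=6 * SEG_N * 3)
        rec = EegRecording(channels=[("C3-A2", sig), ("C4-A1", sig.copy())],
                           sampling_rate=FS)
        s = participant_summary(rec, Hypnogram(("W", "N2", "W")))
        assert s.epoch_counts == {"total": 1, "nrem": 1, "rem": 0}
        assert s.log_power["rem"]["alpha"] is None
        assert s.log_power["total"]["alpha"] is not None

    def test_all_wake_night_flagged_absent_everywhere(self, rng):
        sig = rng.normal(size=6 * SEG_N * 2)
        rec = EegRecording(channels=[("C3-A2", sig), ("C4-A1", sig.copy())],
                           sampling_rate=FS)
        s = participant_summary(rec, Hypnogram(("W", "W")))
        assert all(v is None for state in s.log_power.values()
                   for v in state.values())

    def test_nrem_rem_power_ratio_recovered(self):
        """NREM alpha at 2x REM alpha shows up as a log10(2) state difference."""
        from sleepqeeg.synthetic import generate_stage_eeg

        ninf = float("-inf")
        base = {"delta": ninf, "theta": ninf, "sigma": ninf, "beta": ninf}
        profile = {"N2": {**base, "alpha": np.log10(2.0)},
                   "R": {**base, "alpha": 0.0}}
        hyp = Hypnogram(tuple(["N2", "R"] * 40))
        rec = generate_stage_eeg(hyp, profile, sampling_rate=FS, seed=9)
        s = participant_summary(rec, hyp)
        diff = s.log_power["nrem"]["alpha"] - s.log_power["rem"]["alpha"]
        assert diff == pytest.approx(np.log10(2.0), abs=0.05)
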