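"""FFT band-power spectral analysis of sleep EEG.

The estimator: each 30-s epoch of sleep is split into six contiguous
5-s segments; each segment is mean-removed, Hanning-tapered and Fourier
transformed, giving a one-sided power spectrum on a 0.2 Hz grid
(1 / 5 s).  Band power is the sum of bin powers whose centre frequency
falls in the half-open band interval, excluding everything below
0.8 Hz to guard against sweat/respiration artifact.  Epoch band power
is the mean over the six segments, then the two central derivations are
averaged at the band-power level ([C3-A2 + C4-A1] / 2).  Participant
summaries aggregate epochs by sleep state -- NREM (N1+N2+N3), REM, and
TOTAL (their union; wake excluded) -- as log10 of the mean epoch band
power.

Normalisation follows the Welch convention: spectra are divided by the
window's mean-square value, so for stationary noise the total one-sided
power estimates the signal variance (Parseval-consistent, in uV^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .edf_io import EegRecording
from .hypnogram import Hypnogram, NREM_STAGES, REM, STAGES, WAKE

SEGMENT_SECONDS = 5
SEGMENTS_PER_EPOCH = 6
EPOCH_SECONDS = SEGMENT_SECONDS * SEGMENTS_PER_EPOCH
DEFAULT_MIN_FREQ = 0.8

#: Sleep states a participant summary is stratified by.
TOTAL = "total"
NREM = "nrem"
REM_STATE = "rem"
STATES = (TOTAL, NREM, REM_STATE)

BAND_NAMES = ("delta", "theta", "alpha", "sigma", "beta")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open interval [lo, hi) in Hz.

    Shared edges belong to the upper band (a 4.0 Hz bin is theta, not
    delta), so the five default bands tile [1, 20) Hz without double
    counting.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


_DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 15.0),
    BandDefinition("beta", 15.0, 20.0),
)


def default_bands() -> Tuple[BandDefinition, ...]:
    """delta [1,4), theta [4,8), alpha [8,12), sigma [12,15), beta [15,20)."""
    return _DEFAULT_BANDS


@dataclass(frozen=True)
class SegmentSpectrum:
    """One-sided power spectrum of a 5-s segment (uV^2 per 0.2 Hz bin)."""

    freqs: np.ndarray
    power: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class EpochBandPower:
    """Channel-averaged band powers of one 30-s epoch."""

    epoch_index: int
    stage: str
    band_power: Dict[str, float]


@dataclass
class ParticipantSpectralSummary:
    """log10 absolute band power per sleep state, plus epoch counts.

    ``log_power[state][band]`` is log10 of the mean epoch band power
    (uV^2) over that state's epochs; ``None`` where the state has no
    epochs.
    """

    log_power: Dict[str, Dict[str, Optional[float]]]
    epoch_counts: Dict[str, int]

    def to_rows(self, participant_id=None) -> List[dict]:
        rows = []
        for state in STATES:
            for band, value in self.log_power[state].items():
                rows.append({
                    "participant_id": participant_id,
                    "state": state,
                    "band": band,
                    "log10_power": value,
                    "n_epochs": self.epoch_counts[state],
                })
        return rows


def hanning_window(n: int) -> np.ndarray:
    """Periodic Hanning taper, the standard choice for spectral averaging."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def compute_segment_spectrum(segment: np.ndarray, sampling_rate: float) -> SegmentSpectrum:
    """Windowed one-sided power spectrum of a single 5-s segment.

    The segment is mean-removed (suppresses DC leakage into the
    >=0.8 Hz analysis range), Hanning-tapered, and transformed; powers
    are scaled by 1 / (N * sum(w^2)) and folded one-sided so the total
    power of stationary noise estimates its variance.

    Raises
    ------
    ValueError
        If the segment is not exactly ``5 s * sampling_rate`` samples.
        No implicit padding is performed.
    """
    segment = np.asarray(segment, dtype=float)
    n_expected = round(SEGMENT_SECONDS * sampling_rate)
    if segment.ndim != 1 or segment.size != n_expected:
        raise ValueError(
            f"segment must be exactly {SEGMENT_SECONDS} s x {sampling_rate} Hz "
            f"= {n_expected} samples, got shape {segment.shape}"
        )
    n = segment.size
    w = hanning_window(n)
    x = (segment - segment.mean()) * w
    spec = np.fft.rfft(x)
    power = (spec.real ** 2 + spec.imag ** 2) / (n * np.sum(w ** 2))
    # fold: double everything but DC (and Nyquist when n is even)
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return SegmentSpectrum(freqs=freqs, power=power)


def band_power(spectrum: SegmentSpectrum, band: BandDefinition,
               min_freq: float = DEFAULT_MIN_FREQ) -> float:
    """Integrated power in ``band``: sum of bins with lo <= f < hi, f >= min_freq."""
    f = spectrum.freqs
    mask = (f >= band.lo) & (f < band.hi) & (f >= min_freq)
    return float(np.sum(spectrum.power[mask]))


def epoch_band_powers(epoch: np.ndarray, stage: str,
                      bands: Sequence[BandDefinition] = _DEFAULT_BANDS,
                      sampling_rate: float = 125.0,
                      min_freq: float = DEFAULT_MIN_FREQ,
                      epoch_index: int = 0) -> EpochBandPower:
    """Band powers of one 30-s, two-channel epoch.

    Per channel and band, the band power of each of the six 5-s
    segments is averaged arithmetically; the two channels are then
    averaged at the band-power level.

    Parameters
    ----------
    epoch : ndarray, shape (2, 30 * sampling_rate)
        The two central derivations, in uV.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    epoch = np.asarray(epoch, dtype=float)
    seg_len = round(SEGMENT_SECONDS * sampling_rate)
    n_expected = SEGMENTS_PER_EPOCH * seg_len
    if epoch.ndim != 2 or epoch.shape[0] != 2 or epoch.shape[1] != n_expected:
        raise ValueError(
            f"epoch must have shape (2, {n_expected}) "
            f"({SEGMENTS_PER_EPOCH} x {SEGMENT_SECONDS}-s segments per channel), "
            f"got {epoch.shape}"
        )
    per_channel = np.zeros((2, len(bands)))
    for ch in range(2):
        seg_powers = np.zeros((SEGMENTS_PER_EPOCH, len(bands)))
        for s in range(SEGMENTS_PER_EPOCH):
            spec = compute_segment_spectrum(
                epoch[ch, s * seg_len:(s + 1) * seg_len], sampling_rate)
            for b, band in enumerate(bands):
                seg_powers[s, b] = band_power(spec, band, min_freq)
        per_channel[ch] = seg_powers.mean(axis=0)
    averaged = per_channel.mean(axis=0)
    return EpochBandPower(
        epoch_index=epoch_index,
        stage=stage,
        band_power={band.name: float(averaged[b]) for b, band in enumerate(bands)},
    )


def participant_summary(recording: EegRecording, hypnogram: Hypnogram,
                        bands: Sequence[BandDefinition] = _DEFAULT_BANDS,
                        min_freq: float = DEFAULT_MIN_FREQ) -> ParticipantSpectralSummary:
    """Stage-stratified spectral summary of one participant's night.

    Epochs staged N1/N2/N3 form the NREM set, R the REM set, and their
    union the TOTAL sleep set; wake epochs are excluded.  Per state and
    band the summary is log10 of the arithmetic mean of epoch band
    powers.  Epoch k covers samples [k*30*fs, (k+1)*30*fs); a trailing
    epoch not fully covered by signal is discarded.
    """
    fs = recording.sampling_rate
    epoch_samples = round(EPOCH_SECONDS * fs)
    c3, c4 = recording.central_pair()
    n_full = min(len(hypnogram), len(c3) // epoch_samples)
    if len(c3) < len(hypnogram) * epoch_samples:
        import logging
        logging.getLogger(__name__).info(
            "recording covers %d of %d hypnogram epochs; trailing epochs discarded",
            n_full, len(hypnogram))

    state_powers: Dict[str, List[np.ndarray]] = {NREM: [], REM_STATE: []}
    for k in range(n_full):
        stage = hypnogram.stages[k]
        if stage == WAKE:
            continue
        sl = slice(k * epoch_samples, (k + 1) * epoch_samples)
        ep = epoch_band_powers(np.stack([c3[sl], c4[sl]]), stage, bands,
                               sampling_rate=fs, min_freq=min_freq, epoch_index=k)
        vec = np.array([ep.band_power[b.name] for b in bands])
        state_powers[NREM if stage in NREM_STAGES else REM_STATE].append(vec)

    log_power: Dict[str, Dict[str, Optional[float]]] = {}
    epoch_counts: Dict[str, int] = {}
    groups = {
        NREM: state_powers[NREM],
        REM_STATE: state_powers[REM_STATE],
        TOTAL: state_powers[NREM] + state_powers[REM_STATE],
    }
    for state in STATES:
        vecs = groups[state]
        epoch_counts[state] = len(vecs)
        if vecs:
            mean_power = np.mean(np.stack(vecs), axis=0)
            with np.errstate(divide="ignore"):
                logs = np.log10(mean_power)
            log_power[state] = {
                band.name: float(logs[b]) for b, band in enumerate(bands)}
        else:
            log_power[state] = {band.name: None for band in bands}
    return ParticipantSpectralSummary(log_power=log_power, epoch_counts=epoch_counts)
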