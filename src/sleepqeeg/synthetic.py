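"""Synthetic polysomnography cohorts.

Two tiers, matched to what each downstream stage needs:

* **Feature tier** -- a participant table at full cohort size (default
  group sizes 1386 / 401 / 133 / 65 for NI / INH / HNI / HI) with
  questionnaire responses, covariates and per-state band log-powers
  drawn around group-specific targets.  This validates the group
  classification and the statistical machinery.
* **Raw tier** -- full EEG (two central channels at 125 Hz) plus a
  hypnogram for a handful of participants, synthesised as band-limited
  Gaussian noise whose expected integrated band power hits the
  configured log10 targets.  This validates the spectral chain
  end-to-end.  Full-cohort raw EEG (~2000 nights of two-channel signal)
  is deliberately out of scope; short recordings suffice to exercise
  every code path.

Band log-power targets and covariate distributions default to the
group-wise means/SDs of the study cohort the package emulates;
between-participant spread is Gaussian per band.  Within each band the
synthesised spectrum is flat -- the simplest shape with a closed-form
expected band power.  Covariate-to-EEG coefficients default to zero
and can be switched on for confounding experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .edf_io import C3A2, C4A1, EegRecording
from .grouping import EXCLUDED, GROUPS, QUESTION_COLUMNS, classify_groups
from .hypnogram import Hypnogram, N1, N2, N3, REM, STAGES, WAKE
from .spectral import BAND_NAMES, NREM, REM_STATE, STATES, TOTAL, default_bands


class SyntheticConfigError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


# --- defaults: the emulated study conditions -----------------------------

DEFAULT_GROUP_SIZES: Dict[str, int] = {"NI": 1386, "INH": 401, "HNI": 133, "HI": 65}

#: log10 band power (log10 uV^2) per state x band x group
DEFAULT_BAND_PROFILE: Dict[str, Dict[str, Dict[str, float]]] = {
    TOTAL: {
        "delta": {"NI": 1.419, "INH": 1.447, "HNI": 1.391, "HI": 1.462},
        "theta": {"NI": 0.808, "INH": 0.843, "HNI": 0.804, "HI": 0.872},
        "alpha": {"NI": 0.525, "INH": 0.578, "HNI": 0.567, "HI": 0.661},
        "sigma": {"NI": 0.224, "INH": 0.273, "HNI": 0.297, "HI": 0.387},
        "beta":  {"NI": -0.192, "INH": -0.153, "HNI": -0.133, "HI": -0.076},
    },
    NREM: {
        "delta": {"NI": 1.478, "INH": 1.505, "HNI": 1.446, "HI": 1.511},
        "theta": {"NI": 0.846, "INH": 0.882, "HNI": 0.841, "HI": 0.907},
        "alpha": {"NI": 0.560, "INH": 0.614, "HNI": 0.603, "HI": 0.694},
        "sigma": {"NI": 0.258, "INH": 0.308, "HNI": 0.330, "HI": 0.420},
        "beta":  {"NI": -0.196, "INH": -0.157, "HNI": -0.141, "HI": -0.085},
    },
    REM_STATE: {
        "delta": {"NI": 1.002, "INH": 1.039, "HNI": 1.018, "HI": 1.058},
        "theta": {"NI": 0.585, "INH": 0.618, "HNI": 0.590, "HI": 0.632},
        "alpha": {"NI": 0.319, "INH": 0.357, "HNI": 0.326, "HI": 0.405},
        "sigma": {"NI": 0.025, "INH": 0.066, "HNI": 0.064, "HI": 0.137},
        "beta":  {"NI": -0.202, "INH": -0.154, "HNI": -0.134, "HI": -0.058},
    },
}

#: between-participant SD of log10 band power
DEFAULT_RESIDUAL_SD: Dict[str, float] = {
    "delta": 0.195, "theta": 0.210, "alpha": 0.233, "sigma": 0.214, "beta": 0.190,
}

#: per-group covariate distribution parameters
DEFAULT_COVARIATE_MODEL: Dict[str, Dict[str, Tuple[float, ...]]] = {
    # (mean, sd) for continuous, (p,) for Bernoulli
    "age":             {"NI": (63.5, 11.4), "INH": (64.3, 10.9), "HNI": (65.5, 11.0), "HI": (65.6, 11.1)},
    "sex_female":      {"NI": (0.439,), "INH": (0.651,), "HNI": (0.647,), "HI": (0.831,)},
    "bmi":             {"NI": (28.0, 5.1), "INH": (28.1, 5.1), "HNI": (28.3, 5.6), "HI": (28.6, 5.5)},
    "ahi":             {"NI": (14.9, 15.1), "INH": (14.2, 14.9), "HNI": (13.0, 15.8), "HI": (10.6, 12.2)},
    "current_smoking": {"NI": (0.084,), "INH": (0.107,), "HNI": (0.113,), "HI": (0.092,)},
    "alcohol_per_day": {"NI": (2.8, 5.4), "INH": (2.6, 5.8), "HNI": (2.2, 4.7), "HI": (1.2, 2.7)},
    "tca":             {"NI": (0.010,), "INH": (0.025,), "HNI": (0.165,), "HI": (0.169,)},
    "non_tca":         {"NI": (0.022,), "INH": (0.050,), "HNI": (0.286,), "HI": (0.077,)},
    "benzodiazepine":  {"NI": (0.014,), "INH": (0.107,), "HNI": (0.323,), "HI": (0.431,)},
    "ess":             {"NI": (7.5, 4.5), "INH": (7.6, 4.7), "HNI": (7.2, 4.1), "HI": (6.6, 4.8)},
}

BERNOULLI_COVARIATES = ("sex_female", "current_smoking", "tca", "non_tca",
                        "benzodiazepine")
NONNEGATIVE_COVARIATES = ("ahi", "ess")
GAMMA_COVARIATES = ("alcohol_per_day",)


@dataclass(frozen=True)
class HypnogramModel:
    """First-order Markov model over the five sleep stages.

    The default transition matrix was chosen so its stationary
    distribution reproduces typical cohort sleep architecture (roughly
    4 / 57 / 20 / 19 % of sleep in N1 / N2 / N3 / REM, ~11% wake).
    ``start`` defaults to the stationary distribution, avoiding an
    initialisation transient in stage fractions.
    """

    stages: Tuple[str, ...] = STAGES
    transition: Tuple[Tuple[float, ...], ...] = (
        (0.820, 0.090, 0.090, 0.000, 0.000),   # W
        (0.080, 0.450, 0.420, 0.000, 0.050),   # N1
        (0.020, 0.013, 0.897, 0.042, 0.028),   # N2
        (0.008, 0.000, 0.105, 0.877, 0.010),   # N3
        (0.035, 0.025, 0.045, 0.000, 0.895),   # R
    )
    start: Optional[Tuple[float, ...]] = None

    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition, dtype=float)

    def validate(self) -> None:
        m = self.matrix()
        if m.shape != (len(self.stages), len(self.stages)):
            raise SyntheticConfigError(
                f"hypnogram_model.transition must be {len(self.stages)}x"
                f"{len(self.stages)}, got {m.shape}")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise SyntheticConfigError(
                "hypnogram_model.transition rows must be non-negative and sum to 1")
        if self.start is not None:
            s = np.asarray(self.start, dtype=float)
            if s.shape != (len(self.stages),) or (s < 0).any() or \
                    not np.isclose(s.sum(), 1.0, atol=1e-9):
                raise SyntheticConfigError(
                    "hypnogram_model.start must be a probability vector")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left unit eigenvector)."""
        m = self.matrix()
        w, v = np.linalg.eig(m.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        s = np.real(v[:, i])
        s = np.abs(s)
        return s / s.sum()

    def start_distribution(self) -> np.ndarray:
        if self.start is not None:
            return np.asarray(self.start, dtype=float)
        return self.stationary()


def default_hypnogram_model() -> HypnogramModel:
    return HypnogramModel()


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic cohort.

    Defaults are the emulated study conditions: group sizes
    1386/401/133/65, band log-power targets and SDs from the cohort's
    group-wise summaries, covariate distributions per group, a Markov
    hypnogram model, and 125 Hz sampling.
    """

    group_sizes: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    band_logpower_profile: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: {s: {b: dict(g) for b, g in bands.items()}
                                 for s, bands in DEFAULT_BAND_PROFILE.items()})
    residual_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    covariate_model: Dict[str, Dict[str, Tuple[float, ...]]] = field(
        default_factory=lambda: {c: dict(g) for c, g in DEFAULT_COVARIATE_MODEL.items()})
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    hypnogram_model: HypnogramModel = field(default_factory=HypnogramModel)
    recording_epochs: int = 960          # 8 h night
    sampling_rate: float = 125.0
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise SyntheticConfigError(f"group_sizes: unknown group {g!r}")
            if n < 0:
                raise SyntheticConfigError(f"group_sizes[{g}] must be >= 0, got {n}")
        if sum(n > 0 for n in self.group_sizes.values()) < 2:
            raise SyntheticConfigError(
                "group_sizes: at least two groups must be nonzero")
        for band, sd in self.residual_sd.items():
            if not sd > 0:
                raise SyntheticConfigError(
                    f"residual_sd[{band}] must be > 0, got {sd}")
        highest_edge = max(b.hi for b in default_bands())
        if not self.sampling_rate > 2 * highest_edge:
            raise SyntheticConfigError(
                f"sampling_rate must exceed twice the highest band edge "
                f"({2 * highest_edge} Hz), got {self.sampling_rate}")
        if self.recording_epochs < 1:
            raise SyntheticConfigError("recording_epochs must be >= 1")
        self.hypnogram_model.validate()


@dataclass
class SyntheticCohort:
    """A generated cohort: participant table, optional raw recordings, truth."""

    participants: pd.DataFrame
    truth: SyntheticConfig
    recordings: Optional[Dict[object, Tuple[EegRecording, Hypnogram]]] = None


# --- questionnaire sampling ----------------------------------------------

def _sample_q123_with_five(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform over {1..5}^3 conditioned on at least one item being 5."""
    out = rng.integers(1, 6, size=(n, 3))
    bad = ~(out == 5).any(axis=1)
    while bad.any():
        out[bad] = rng.integers(1, 6, size=(int(bad.sum()), 3))
        bad = ~(out == 5).any(axis=1)
    return out


def _sample_responses(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    q = np.empty((n, 4), dtype=int)
    if group == "NI":
        q[:] = rng.integers(1, 3, size=(n, 4))
    elif group == "INH":
        q[:, :3] = _sample_q123_with_five(rng, n)
        q[:, 3] = rng.integers(1, 3, size=n)
    elif group == "HNI":
        q[:, :3] = rng.integers(1, 3, size=(n, 3))
        q[:, 3] = 5
    elif group == "HI":
        q[:, :3] = _sample_q123_with_five(rng, n)
        q[:, 3] = 5
    else:  # pragma: no cover
        raise SyntheticConfigError(f"cannot sample responses for group {group!r}")
    return q


def _sample_covariate(rng: np.random.Generator, name: str,
                      params: Tuple[float, ...], n: int) -> np.ndarray:
    if name in BERNOULLI_COVARIATES:
        (p,) = params
        return (rng.random(n) < p).astype(int)
    mean, sd = params
    if name in GAMMA_COVARIATES:
        # right-skewed, non-negative (sd may exceed the mean)
        if mean <= 0:
            return np.zeros(n)
        shape = (mean / sd) ** 2
        return rng.gamma(shape, scale=sd ** 2 / mean, size=n)
    x = rng.normal(mean, sd, size=n)
    if name == "age":
        x = np.clip(x, 40.0, None)       # cohort restricted to adults over 40
    elif name in NONNEGATIVE_COVARIATES:
        x = np.clip(x, 0.0, None)
    return x


def generate_feature_cohort(config: Optional[SyntheticConfig] = None,
                            seed: Optional[int] = None) -> SyntheticCohort:
    """Generate the feature-tier participant table.

    Per participant: a questionnaire response sampled uniformly among
    the vectors consistent with the generating group's rule, covariates
    from the group's distribution, and per-state band log-powers drawn
    as group target + Gaussian noise (``residual_sd``), plus optional
    linear covariate contributions.  Deterministic given
    ``config.seed`` (or the ``seed`` override).
    """
    config = config if config is not None else SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    frames: List[pd.DataFrame] = []
    offset = 0
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        q = _sample_responses(rng, group, n)
        data = {
            "participant_id": [f"SYN{offset + i:05d}" for i in range(n)],
            "group": group,
        }
        for j, col in enumerate(QUESTION_COLUMNS):
            data[col] = q[:, j]
        for cov, per_group in config.covariate_model.items():
            data[cov] = _sample_covariate(rng, cov, per_group[group], n)
        frame = pd.DataFrame(data)

        effect = np.zeros(n)
        for cov, coef in config.covariate_effects.items():
            if coef:
                effect = effect + coef * frame[cov].to_numpy(dtype=float)
        for state in STATES:
            for band in BAND_NAMES:
                target = config.band_logpower_profile[state][band][group]
                sd = config.residual_sd[band]
                frame[f"{state}_{band}"] = (
                    target + effect + rng.normal(0.0, sd, size=n))
        frames.append(frame)
        offset += n

    participants = pd.concat(frames, ignore_index=True)
    derived = classify_groups(participants)
    if not (derived == participants["group"]).all():  # pragma: no cover
        raise AssertionError("generated responses do not classify to their group")
    return SyntheticCohort(participants=participants, truth=config)


# --- raw tier -------------------------------------------------------------

def generate_hypnogram(model: Optional[HypnogramModel] = None,
                       n_epochs: int = 960,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> Hypnogram:
    """Simulate a first-order Markov stage sequence of ``n_epochs`` epochs."""
    model = model if model is not None else HypnogramModel()
    model.validate()
    if n_epochs < 1:
        raise SyntheticConfigError("n_epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = model.matrix()
    cum = np.cumsum(m, axis=1)
    start_cum = np.cumsum(model.start_distribution())
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=int)
    states[0] = int(np.searchsorted(start_cum, u[0], side="right"))
    for k in range(1, n_epochs):
        states[k] = int(np.searchsorted(cum[states[k - 1]], u[k], side="right"))
    return Hypnogram(tuple(model.stages[i] for i in states))


def generate_hypnograms_batch(model: Optional[HypnogramModel],
                              n_participants: int, n_epochs: int,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None
                              ) -> List[Hypnogram]:
    """Simulate many independent Markov stage sequences at once.

    Vectorised across participants (one matrix lookup per epoch), so a
    full cohort of nights stays cheap.
    """
    model = model if model is not None else HypnogramModel()
    model.validate()
    if n_epochs < 1 or n_participants < 1:
        raise SyntheticConfigError("n_participants and n_epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cum = np.cumsum(model.matrix(), axis=1)
    start_cum = np.cumsum(model.start_distribution())
    states = np.empty((n_participants, n_epochs), dtype=int)
    states[:, 0] = np.searchsorted(start_cum, rng.random(n_participants),
                                   side="right")
    for k in range(1, n_epochs):
        u = rng.random(n_participants)
        states[:, k] = (u[:, None] >= cum[states[:, k - 1]]).sum(axis=1)
    return [Hypnogram(tuple(model.stages[i] for i in row)) for row in states]


def _band_bin_amplitudes(profile_row: Mapping[str, float], n: int,
                         epoch_seconds: float,
                         bands=None) -> np.ndarray:
    """Per-rFFT-bin amplitude so each band's expected power is 10^target."""
    bands = bands if bands is not None else default_bands()
    nb = n // 2 + 1
    amp = np.zeros(nb)
    for band in bands:
        if band.name not in profile_row:
            raise SyntheticConfigError(
                f"band_logpower_profile missing band {band.name!r}")
        target = profile_row[band.name]
        power = 0.0 if np.isneginf(target) else 10.0 ** target
        k_lo = int(np.ceil(band.lo * epoch_seconds - 1e-9))
        k_hi = int(np.ceil(band.hi * epoch_seconds - 1e-9))   # exclusive
        k_hi = min(k_hi, nb)
        m = k_hi - k_lo
        if m <= 0:
            raise SyntheticConfigError(
                f"band {band.name} has no FFT bins at this epoch length")
        amp[k_lo:k_hi] = np.sqrt(n ** 2 * power / (2.0 * m))
    return amp


def generate_stage_eeg(hypnogram: Hypnogram,
                       band_logpower_profile: Mapping[str, Mapping[str, float]],
                       sampling_rate: float = 125.0,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       drift_amplitude_uv: float = 0.0,
                       drift_freq_hz: float = 0.3) -> EegRecording:
    """Synthesise a two-channel EEG matching per-stage band-power targets.

    Per 30-s epoch, the signal is a sum of independent band-limited
    Gaussian processes shaped in the FFT domain (flat within each
    band), scaled so the expected integrated band power in uV^2 equals
    ``10 ** target`` for the epoch's stage.  The two channels are
    independent realisations of the same profile.  An optional
    sub-0.8 Hz sinusoidal drift (shared across channels, added after
    the stochastic draw so it does not perturb the noise stream) can be
    injected to exercise the low-frequency exclusion.

    ``band_logpower_profile`` maps stage -> band -> log10 uV^2 target
    and must cover every stage present in the hypnogram; use ``-inf``
    for a band with zero power.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = round(hypnogram.epoch_seconds * fs)
    nb = n // 2 + 1
    present = sorted(set(hypnogram.stages))
    missing = [s for s in present if s not in band_logpower_profile]
    if missing:
        raise SyntheticConfigError(
            f"band_logpower_profile missing stage(s) {missing}")
    amp_by_stage = {s: _band_bin_amplitudes(band_logpower_profile[s], n,
                                            hypnogram.epoch_seconds)
                    for s in present}
    stage_idx = np.array([present.index(s) for s in hypnogram.stages])
    amp = np.stack([amp_by_stage[s] for s in present])[stage_idx]  # (E, nb)

    n_epochs = len(hypnogram)
    channels = []
    for label in (C3A2, C4A1):
        z = (rng.standard_normal((n_epochs, nb))
             + 1j * rng.standard_normal((n_epochs, nb))) / np.sqrt(2.0)
        signal = np.fft.irfft(amp * z, n=n, axis=1).ravel()
        channels.append((label, signal))
    if drift_amplitude_uv:
        t = np.arange(n_epochs * n) / fs
        drift = drift_amplitude_uv * np.sin(2.0 * np.pi * drift_freq_hz * t)
        channels = [(lab, sig + drift) for lab, sig in channels]
    return EegRecording(channels=channels, sampling_rate=fs)


def stage_profile_for_group(config: SyntheticConfig, group: str
                            ) -> Dict[str, Dict[str, float]]:
    """Map the per-state band targets onto hypnogram stages for one group.

    N1/N2/N3 (and wake, whose epochs are excluded from analysis anyway)
    use the NREM targets; R uses the REM targets.
    """
    nrem_row = {b: config.band_logpower_profile[NREM][b][group] for b in BAND_NAMES}
    rem_row = {b: config.band_logpower_profile[REM_STATE][b][group] for b in BAND_NAMES}
    return {WAKE: dict(nrem_row), N1: dict(nrem_row), N2: dict(nrem_row),
            N3: dict(nrem_row), REM: dict(rem_row)}


def add_raw_recordings(cohort: SyntheticCohort,
                       participant_ids: Optional[Sequence[object]] = None,
                       n_epochs: int = 120,
                       seed: int = 0) -> SyntheticCohort:
    """Attach raw-tier (EEG, hypnogram) pairs for selected participants.

    Defaults to one participant per group and 1-h recordings; the
    recording duration always equals ``n_epochs * 30 s``.
    """
    df = cohort.participants
    if participant_ids is None:
        participant_ids = [df[df["group"] == g]["participant_id"].iloc[0]
                           for g in GROUPS if (df["group"] == g).any()]
    rng = np.random.default_rng(seed)
    recordings = dict(cohort.recordings or {})
    for pid in participant_ids:
        row = df[df["participant_id"] == pid]
        if row.empty:
            raise KeyError(f"participant {pid!r} not in cohort")
        group = row["group"].iloc[0]
        hyp = generate_hypnogram(cohort.truth.hypnogram_model, n_epochs, rng=rng)
        rec = generate_stage_eeg(hyp, stage_profile_for_group(cohort.truth, group),
                                 sampling_rate=cohort.truth.sampling_rate, rng=rng)
        recordings[pid] = (rec, hyp)
    cohort.recordings = recordings
    return cohort
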