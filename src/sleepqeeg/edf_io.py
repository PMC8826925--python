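"""EDF and hypnogram file I/O.

Signals travel as plain EDF (16-bit, 1-s data records, physical
dimension uV); hypnograms as single-column text/CSV.  Reading EDF goes
through :mod:`mne`; writing is done directly, since the analysis only
needs the plain-EDF subset (no annotations, uniform record layout).

Only the two central referential derivations C3-A2 and C4-A1 are
retained on read -- they are what the spectral analysis consumes; other
channels are ignored with a logged notice.  Channel labels are matched
case-insensitively after stripping punctuation, so "EEG C3-A2", "C3/A2"
and "c3a2" all resolve to the same derivation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .hypnogram import Hypnogram

logger = logging.getLogger(__name__)

C3A2 = "C3-A2"
C4A1 = "C4-A1"

DEFAULT_PHYSICAL_RANGE_UV = 500.0
# symmetric digital range so 0 uV is exactly representable
_DIGITAL_MIN = -32767
_DIGITAL_MAX = 32767


class EdfFormatError(ValueError):
    """Raised for malformed or incomplete EDF content."""


class HypnogramFormatError(ValueError):
    """Raised for unparseable hypnogram files."""


def _normalize_label(label: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", label.upper())


@dataclass
class EegRecording:
    """Two-channel central EEG in microvolts at a fixed sampling rate."""

    channels: List[Tuple[str, np.ndarray]]
    sampling_rate: float
    start_time: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {len(sig) for _, sig in self.channels}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        norms = [_normalize_label(lab) for lab, _ in self.channels]
        for required in (C3A2, C4A1):
            key = _normalize_label(required)
            if not any(key in n for n in norms):
                raise ValueError(
                    f"required derivation {required} absent; channels present: "
                    f"{[lab for lab, _ in self.channels]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.channels[0][1])

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate

    def central_pair(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (C3-A2, C4-A1) signals in uV, in that order."""
        out = {}
        for lab, sig in self.channels:
            n = _normalize_label(lab)
            for required in (C3A2, C4A1):
                if _normalize_label(required) in n and required not in out:
                    out[required] = np.asarray(sig, dtype=float)
        return out[C3A2], out[C4A1]


def read_edf(path) -> EegRecording:
    """Read an EDF file, returning the two central derivations in uV.

    Raises
    ------
    EdfFormatError
        If the file is not valid EDF or a required central derivation
        is missing (the error lists the labels that are present).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt headers
        raise EdfFormatError(f"cannot parse EDF file {path}: {exc}") from exc

    wanted = {_normalize_label(C3A2): C3A2, _normalize_label(C4A1): C4A1}
    picks: dict = {}
    ignored = []
    for name in raw.ch_names:
        norm = _normalize_label(name)
        hit = next((canon for key, canon in wanted.items() if key in norm), None)
        if hit is not None and hit not in picks:
            picks[hit] = name
        else:
            ignored.append(name)
    missing = [canon for canon in (C3A2, C4A1) if canon not in picks]
    if missing:
        raise EdfFormatError(
            f"EDF {path} lacks required derivation(s) {missing}; "
            f"available channels: {raw.ch_names}"
        )
    if ignored:
        logger.info("read_edf(%s): ignoring %d non-central channel(s): %s",
                    path, len(ignored), ignored)
    data = raw.get_data(picks=[picks[C3A2], picks[C4A1]], units="uV")
    meas = raw.info.get("meas_date")
    return EegRecording(
        channels=[(C3A2, data[0]), (C4A1, data[1])],
        sampling_rate=float(raw.info["sfreq"]),
        start_time=str(meas) if meas is not None else None,
    )


def write_edf(recording: EegRecording, path,
              physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV) -> None:
    """Write a recording as plain EDF (16-bit, 1-s records, uV).

    The sampling rate must be a whole number of samples per second; a
    trailing partial second is discarded.  Samples outside
    ``+/- physical_range_uv`` raise a range error rather than clipping
    silently.
    """
    fs = recording.sampling_rate
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate (1-s records)")
    fs = int(fs)
    ns = len(recording.channels)
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    for lab, sig in recording.channels:
        peak = float(np.max(np.abs(sig))) if len(sig) else 0.0
        if peak > physical_range_uv:
            raise ValueError(
                f"channel {lab} amplitude {peak:.1f} uV exceeds physical range "
                f"+/-{physical_range_uv} uV"
            )

    def f(value, width: int) -> bytes:
        s = str(value).encode("ascii")
        if len(s) > width:
            raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
        return s.ljust(width)

    header = b"".join([
        f("0", 8),                      # version
        f("", 80),                      # patient id
        f("", 80),                      # recording id
        f("01.01.00", 8),               # start date
        f("00.00.00", 8),               # start time
        f(256 * (ns + 1), 8),           # header bytes
        f("", 44),                      # reserved
        f(n_records, 8),
        f(1, 8),                        # record duration, s
        f(ns, 4),
    ])
    labels = [lab for lab, _ in recording.channels]
    header += b"".join(f(lab, 16) for lab in labels)
    header += b"".join(f("", 80) for _ in labels)            # transducer
    header += b"".join(f("uV", 8) for _ in labels)           # physical dimension
    header += b"".join(f(-physical_range_uv, 8) for _ in labels)
    header += b"".join(f(physical_range_uv, 8) for _ in labels)
    header += b"".join(f(_DIGITAL_MIN, 8) for _ in labels)
    header += b"".join(f(_DIGITAL_MAX, 8) for _ in labels)
    header += b"".join(f("", 80) for _ in labels)            # prefiltering
    header += b"".join(f(fs, 8) for _ in labels)             # samples per record
    header += b"".join(f("", 32) for _ in labels)            # reserved

    gain = (2.0 * physical_range_uv) / (_DIGITAL_MAX - _DIGITAL_MIN)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for _, sig in recording.channels:
                seg = np.asarray(sig[r * fs:(r + 1) * fs], dtype=float)
                dig = np.round((seg + physical_range_uv) / gain) + _DIGITAL_MIN
                fh.write(dig.astype("<i2").tobytes())


# --- hypnogram text format ----------------------------------------------

_STAGE_TOKENS = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "3": "N3",
    "S4": "N3", "4": "N3",      # R&K stage 4 merged into N3
    "R": "R", "REM": "R", "5": "R",
}


def read_hypnogram(path) -> Hypnogram:
    """Parse a hypnogram: one stage token per line, or comma-separated.

    Accepts the stage alphabet {W, N1, N2, N3, R}, the synonyms
    WAKE/S1..S4/REM, and the R&K numeric codes 0-5 (with S3 and S4 both
    mapping to N3).  A header line ``stage`` is skipped.  Unknown tokens
    raise :class:`HypnogramFormatError` with the offending line number.
    """
    path = Path(path)
    stages: List[str] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            for tok in line.strip().split(","):
                tok = tok.strip().upper()
                if not tok:
                    continue
                if lineno == 1 and tok == "STAGE":
                    continue
                try:
                    stages.append(_STAGE_TOKENS[tok])
                except KeyError:
                    raise HypnogramFormatError(
                        f"{path}:{lineno}: unknown stage token {tok!r}"
                    ) from None
    if not stages:
        raise HypnogramFormatError(f"{path}: no stage tokens found")
    return Hypnogram(tuple(stages))


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    """Write one stage token per line (header ``stage``)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("stage\n")
        for s in hypnogram.stages:
            fh.write(s + "\n")
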