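"""Insomnia/hypnotic group classification and cohort inclusion rules.

Four questionnaire items, each on a 5-point frequency Likert scale
(1 never ... 5 almost always, 16-30 times/month):

  Q1  trouble falling asleep (sleep initiation difficulty)
  Q2  waking during the night with difficulty resuming sleep
  Q3  waking too early, unable to resume sleep
  Q4  taking sleeping pills or other medication to help sleep

Group rules (a response of 5 marks a symptom as present, 1 or 2 as
absent):

  NI   (non-insomnia)          1 or 2 on all four items
  INH  (insomnia, no hypnotic) 5 on at least one of Q1-Q3, 1 or 2 on Q4
  HNI  (hypnotic, no insomnia) 5 on Q4, 1 or 2 on each of Q1-Q3
  HI   (hypnotic + insomnia)   5 on at least one of Q1-Q3, and 5 on Q4

Responses fitting none of the rules are labelled EXCLUDED (an explicit
label, not an error).  The four group rules are mutually exclusive by
construction; see the exhaustive property test over all 625 response
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, N1, N2, N3, REM, WAKE

GROUPS: Tuple[str, ...] = ("NI", "INH", "HNI", "HI")
EXCLUDED = "EXCLUDED"

LIKERT_LEVELS = (1, 2, 3, 4, 5)

QUESTION_COLUMNS = ("q1_initiation", "q2_maintenance", "q3_early_awakening",
                    "q4_sleeping_pills")

#: covariates whose completeness is required for inclusion
MEDICATION_COLUMNS = ("tca", "non_tca", "benzodiazepine")


class MissingResponseError(ValueError):
    """A questionnaire item is missing; the participant cannot be classified."""


@dataclass(frozen=True)
class QuestionnaireResponse:
    q1_initiation: int
    q2_maintenance: int
    q3_early_awakening: int
    q4_sleeping_pills: int

    def __post_init__(self) -> None:
        for name in QUESTION_COLUMNS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise MissingResponseError(f"missing questionnaire item {name}")
            if v not in LIKERT_LEVELS:
                raise ValueError(f"{name}={v!r} outside Likert range 1-5")

    def items(self) -> Tuple[int, int, int, int]:
        return (self.q1_initiation, self.q2_maintenance,
                self.q3_early_awakening, self.q4_sleeping_pills)


def classify_group(response) -> str:
    """Classify one response into NI / INH / HNI / HI / EXCLUDED.

    ``response`` may be a :class:`QuestionnaireResponse` or a sequence
    of four Likert integers (Q1..Q4).
    """
    if not isinstance(response, QuestionnaireResponse):
        response = QuestionnaireResponse(*response)
    q1, q2, q3, q4 = response.items()
    insomnia_any5 = 5 in (q1, q2, q3)
    insomnia_all_low = all(v in (1, 2) for v in (q1, q2, q3))
    if insomnia_all_low and q4 in (1, 2):
        return "NI"
    if insomnia_any5 and q4 in (1, 2):
        return "INH"
    if insomnia_all_low and q4 == 5:
        return "HNI"
    if insomnia_any5 and q4 == 5:
        return "HI"
    return EXCLUDED


def classify_groups(frame: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_group` over a frame with the Q1..Q4 columns."""
    q = frame[list(QUESTION_COLUMNS)].to_numpy()
    any5 = (q[:, :3] == 5).any(axis=1)
    low123 = np.isin(q[:, :3], (1, 2)).all(axis=1)
    q4_low = np.isin(q[:, 3], (1, 2))
    q4_five = q[:, 3] == 5
    out = np.full(len(frame), EXCLUDED, dtype=object)
    out[low123 & q4_low] = "NI"
    out[any5 & q4_low] = "INH"
    out[low123 & q4_five] = "HNI"
    out[any5 & q4_five] = "HI"
    return pd.Series(out, index=frame.index, name="group")


#: inclusion cascade, applied in order; each entry is (reason, columns
#: whose completeness the step requires)
INCLUSION_CASCADE: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("group", ()),                      # classifiable, non-EXCLUDED
    ("spectral", ()),                   # spectral summary columns complete
    ("alcohol", ("alcohol_per_day",)),
    ("medications", MEDICATION_COLUMNS),
    ("smoking", ("current_smoking",)),
)


def apply_inclusion(records: pd.DataFrame,
                    spectral_columns: Optional[Sequence[str]] = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the complete-data inclusion cascade.

    Drops, in order: participants whose responses are missing or do not
    classify into one of the four groups; those missing any spectral
    summary value; then those missing alcohol intake, medication flags,
    or smoking status.  Kept records are returned unmodified (pure
    filter) together with a per-reason drop-count table.

    Parameters
    ----------
    records : DataFrame
        One row per participant, with the questionnaire columns, a
        ``group`` column (recomputed if absent), covariates, and
        spectral summary columns.
    spectral_columns : sequence of str, optional
        Columns whose completeness defines "has spectral data".
        Defaults to every column starting with ``total_``, ``nrem_`` or
        ``rem_``.
    """
    df = records.copy()
    if "group" not in df.columns:
        df["group"] = classify_groups(df)
    if spectral_columns is None:
        spectral_columns = [c for c in df.columns
                            if c.startswith(("total_", "nrem_", "rem_"))]

    keep = pd.Series(True, index=df.index)
    counts: List[dict] = []
    for reason, cols in INCLUSION_CASCADE:
        if reason == "group":
            bad = df["group"].isna() | (df["group"] == EXCLUDED)
            if set(QUESTION_COLUMNS) <= set(df.columns):
                bad |= df[list(QUESTION_COLUMNS)].isna().any(axis=1)
        elif reason == "spectral":
            bad = (df[list(spectral_columns)].isna().any(axis=1)
                   if spectral_columns else pd.Series(False, index=df.index))
        else:
            present = [c for c in cols if c in df.columns]
            bad = (df[present].isna().any(axis=1) if present
                   else pd.Series(False, index=df.index))
        newly = bad & keep
        counts.append({"reason": reason, "n_dropped": int(newly.sum())})
        keep &= ~bad
    cascade = pd.DataFrame(counts)
    kept = records.loc[keep[keep].index]
    dropped = records.loc[keep[~keep].index]
    return kept, cascade.assign(n_kept_after=len(records) - cascade["n_dropped"].cumsum())


@dataclass
class PsgMetrics:
    """Hypnogram-level sleep architecture summary (Table-2-style rows)."""

    time_in_bed_min: float
    total_sleep_time_min: float
    sleep_efficiency_pct: float
    waso_min: Optional[float]
    sleep_onset_min: Optional[float]
    rem_latency_min: Optional[float]
    stage_pct: Dict[str, float]
    epoch_counts: Dict[str, int]


def psg_metrics(hypnogram: Hypnogram,
                time_in_bed_min: Optional[float] = None) -> PsgMetrics:
    """Standard sleep-architecture metrics from a hypnogram.

    Conventions: sleep onset is the first non-wake epoch; WASO counts
    wake epochs after onset; REM latency runs from onset to the first
    REM epoch; stage percentages are of total sleep time.  Latencies
    are ``None`` when undefined (no sleep, or no REM).
    """
    stages = np.array(hypnogram.stages)
    minutes_per_epoch = hypnogram.epoch_seconds / 60.0
    if time_in_bed_min is None:
        time_in_bed_min = len(stages) * minutes_per_epoch
    sleep_mask = stages != WAKE
    n_sleep = int(sleep_mask.sum())
    tst = n_sleep * minutes_per_epoch
    efficiency = 100.0 * tst / time_in_bed_min if time_in_bed_min > 0 else 0.0

    counts = {s: int((stages == s).sum()) for s in (WAKE, N1, N2, N3, REM)}
    if n_sleep == 0:
        return PsgMetrics(time_in_bed_min, 0.0, 0.0, None, None, None,
                          {s: float("nan") for s in (N1, N2, N3, REM)}, counts)

    onset_idx = int(np.argmax(sleep_mask))
    waso = float((stages[onset_idx:] == WAKE).sum()) * minutes_per_epoch
    rem_idx = np.flatnonzero(stages == REM)
    rem_latency = (float(rem_idx[0] - onset_idx) * minutes_per_epoch
                   if len(rem_idx) else None)
    stage_pct = {s: 100.0 * counts[s] / n_sleep for s in (N1, N2, N3, REM)}
    return PsgMetrics(
        time_in_bed_min=time_in_bed_min,
        total_sleep_time_min=tst,
        sleep_efficiency_pct=efficiency,
        waso_min=waso,
        sleep_onset_min=onset_idx * minutes_per_epoch,
        rem_latency_min=rem_latency,
        stage_pct=stage_pct,
        epoch_counts=counts,
    )
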