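"""Per-epoch sleep stage sequences.

A hypnogram is the stage sequence of one night's recording, one stage
per 30-s epoch, over the alphabet Wake / N1 / N2 / N3 / REM.  Slow-wave
stages scored as S3 and S4 under the Rechtschaffen & Kales rules are
both reported as N3, matching modern stage nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

WAKE = "W"
N1 = "N1"
N2 = "N2"
N3 = "N3"
REM = "R"

STAGES: Tuple[str, ...] = (WAKE, N1, N2, N3, REM)
SLEEP_STAGES: Tuple[str, ...] = (N1, N2, N3, REM)
NREM_STAGES: Tuple[str, ...] = (N1, N2, N3)

EPOCH_SECONDS = 30


@dataclass(frozen=True)
class Hypnogram:
    """Stage sequence, one element per 30-s epoch."""

    stages: Tuple[str, ...]
    epoch_seconds: int = field(default=EPOCH_SECONDS)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown sleep stage(s) {bad}; expected one of {STAGES}")
        object.__setattr__(self, "stages", tuple(self.stages))

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterable[str]:
        return iter(self.stages)

    @property
    def duration_seconds(self) -> int:
        return len(self.stages) * self.epoch_seconds

    def count(self, stage: str) -> int:
        return sum(1 for s in self.stages if s == stage)
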