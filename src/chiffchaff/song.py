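"""Rule-based song classification from extracted acoustic features.

Inputs are features already extracted from sonograms: the percentage of
ascending elements in three 3-second song intervals, the note rate
(notes/second), and the note frequency range (kHz). Three criteria are
evaluated against the documented lineage ranges:

* ascending elements: mean 0% → abietinus-like; above a high threshold
  (default 90%) → tristis-like; anything in between → mixed-like;
* note rate: inside [2.8, 3.3] → abietinus-like, inside [4.7, 7.2] →
  tristis-like, else mixed-like (intervals closed — the published
  ranges are descriptive summaries);
* frequency range: contained in [3.7, 4.6] kHz → abietinus-like,
  contained in [2.9, 3.7] kHz → tristis-like, else mixed-like.

The final call is a pure type only when all three criteria agree;
otherwise the bird is a mixed singer — matching the field definition of
mixed song as a mixture of both note types with intermediate rate and
frequency range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import percent_of_total

SONG_TYPES = ("abietinus", "tristis", "mixed")


@dataclass(frozen=True)
class SongFeatures:
    ascending: tuple[float, float, float]  # % ascending elements, 3 intervals
    note_rate: float                       # notes per second
    freq_low: float                        # kHz
    freq_high: float                       # kHz

    def __post_init__(self) -> None:
        if len(self.ascending) != 3:
            raise ValueError("three ascending-element percentages required")
        if any(not 0.0 <= a <= 100.0 for a in self.ascending):
            raise ValueError("ascending percentages must lie in [0, 100]")
        if self.note_rate <= 0:
            raise ValueError("note rate must be positive")
        if not self.freq_low < self.freq_high:
            raise ValueError("frequency range must satisfy low < high")


@dataclass(frozen=True)
class SongCriteria:
    """Classification thresholds; defaults are the documented ranges."""

    abietinus_rate: tuple[float, float] = (2.8, 3.3)
    tristis_rate: tuple[float, float] = (4.7, 7.2)
    abietinus_band: tuple[float, float] = (3.7, 4.6)
    tristis_band: tuple[float, float] = (2.9, 3.7)
    tristis_ascending_min: float = 90.0  # mean % above this is tristis-like


@dataclass(frozen=True)
class SongCall:
    call: str
    ascending_verdict: str
    rate_verdict: str
    frequency_verdict: str


def _in(x: float, interval: tuple[float, float]) -> bool:
    return interval[0] <= x <= interval[1]


def classify_song(
    features: SongFeatures, criteria: SongCriteria = SongCriteria()
) -> SongCall:
    """Classify one male's song as abietinus, tristis, or mixed."""
    mean_asc = float(np.mean(features.ascending))
    if mean_asc == 0.0:
        asc = "abietinus"
    elif mean_asc > criteria.tristis_ascending_min:
        asc = "tristis"
    else:
        asc = "mixed"

    if _in(features.note_rate, criteria.abietinus_rate):
        rate = "abietinus"
    elif _in(features.note_rate, criteria.tristis_rate):
        rate = "tristis"
    else:
        rate = "mixed"

    lo, hi = features.freq_low, features.freq_high
    if _in(lo, criteria.abietinus_band) and _in(hi, criteria.abietinus_band):
        freq = "abietinus"
    elif _in(lo, criteria.tristis_band) and _in(hi, criteria.tristis_band):
        freq = "tristis"
    else:
        freq = "mixed"

    call = asc if asc == rate == freq and asc != "mixed" else "mixed"
    return SongCall(
        call=call, ascending_verdict=asc, rate_verdict=rate, frequency_verdict=freq
    )


def classify_table(
    features: pd.DataFrame, criteria: SongCriteria = SongCriteria()
) -> pd.DataFrame:
    """Classify a feature table (columns ascending_1..3, note_rate,
    freq_low, freq_high); returns the table plus call/verdict columns."""
    out = features.copy()
    calls = []
    for _, row in features.iterrows():
        sc = classify_song(
            SongFeatures(
                ascending=(row["ascending_1"], row["ascending_2"], row["ascending_3"]),
                note_rate=row["note_rate"],
                freq_low=row["freq_low"],
                freq_high=row["freq_high"],
            ),
            criteria,
        )
        calls.append(sc)
    out["call"] = [c.call for c in calls]
    out["ascending_verdict"] = [c.ascending_verdict for c in calls]
    out["rate_verdict"] = [c.rate_verdict for c in calls]
    out["frequency_verdict"] = [c.frequency_verdict for c in calls]
    return out


def tabulate_song(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-region and total counts with one-decimal percentages.

    ``calls`` needs columns ``call`` and ``region``. Regions with zero
    scored songs produce zero-count rows, never a division error.
    """
    regions = list(dict.fromkeys(calls["region"])) if len(calls) else []
    rows = []
    for region in regions + ["total"]:
        sub = calls if region == "total" else calls[calls["region"] == region]
        total = len(sub)
        for t in SONG_TYPES:
            n = int((sub["call"] == t).sum())
            rows.append(
                {
                    "region": region,
                    "call": t,
                    "count": n,
                    "percent": percent_of_total(n, total) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)
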