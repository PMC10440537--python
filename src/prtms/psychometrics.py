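"""Scoring and classification for the weekly symptom questionnaires.

PCL-5 (PTSD checklist for DSM-5): 20 items scored 0-4, total 0-80;
screening cutoff 33.  A drop of strictly more than 5 points from baseline
to final marks a *reliable* treatment response (a responder); a drop of
strictly more than 10 points is *clinically meaningful*.  HAM-A and HAM-D
enter as totals only and are mapped onto the conventional severity bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "PCL5_CUTOFF",
    "RELIABLE_THRESH",
    "MEANINGFUL_THRESH",
    "ScoreSeries",
    "score_pcl5",
    "classify_ptsd",
    "change_from_baseline",
    "classify_responder",
    "severity_band",
]

PCL5_CUTOFF = 33
RELIABLE_THRESH = 5
MEANINGFUL_THRESH = 10

_INSTRUMENT_MAX = {"PCL5": 80, "HAMA": 56, "HAMD": 52}


@dataclass
class ScoreSeries:
    """Weekly totals of one instrument for one subject (baseline = week 0)."""

    subject_id: str
    instrument: Literal["PCL5", "HAMA", "HAMD"]
    totals: dict[int, int]

    def __post_init__(self) -> None:
        if self.instrument not in _INSTRUMENT_MAX:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        weeks = sorted(self.totals)
        if list(self.totals) != weeks:
            self.totals = {w: self.totals[w] for w in weeks}
        if 0 not in self.totals:
            raise ValueError(f"{self.subject_id}/{self.instrument}: baseline "
                             "(week 0) missing")
        hi = _INSTRUMENT_MAX[self.instrument]
        for w, t in self.totals.items():
            if not (0 <= t <= hi):
                raise ValueError(
                    f"{self.subject_id}/{self.instrument}: total {t} at week {w} "
                    f"outside [0, {hi}]"
                )

    @property
    def weeks(self) -> list[int]:
        return sorted(self.totals)

    @property
    def baseline(self) -> int:
        return self.totals[0]

    @property
    def final(self) -> int:
        """Last observed total (last observation carried forward)."""
        return self.totals[self.weeks[-1]]

    def at(self, week: int) -> int:
        if week not in self.totals:
            raise KeyError(f"{self.subject_id}/{self.instrument}: week {week} missing")
        return self.totals[week]


def score_pcl5(items: Sequence[int]) -> int:
    """Total score of the 20-item PCL-5 (each item 0-4)."""
    items = list(items)
    if len(items) != 20:
        raise ValueError(f"PCL-5 has exactly 20 items, got {len(items)}")
    for i, v in enumerate(items):
        if int(v) != v or not (0 <= v <= 4):
            raise ValueError(f"item {i + 1} value {v!r} outside 0-4")
    return int(sum(items))


def classify_ptsd(total: int, cutoff: int = PCL5_CUTOFF) -> Literal["positive", "negative"]:
    """Screening status: positive iff total >= cutoff (default 33)."""
    if not (0 <= total <= 80):
        raise ValueError(f"PCL-5 total {total} outside 0-80")
    return "positive" if total >= cutoff else "negative"


def change_from_baseline(series: ScoreSeries, week: int) -> int:
    """CFB = score(week) - score(baseline); negative = improvement."""
    return series.at(week) - series.baseline


def classify_responder(
    baseline: int,
    final: int,
    reliable_thresh: int = RELIABLE_THRESH,
    meaningful_thresh: int = MEANINGFUL_THRESH,
) -> tuple[Literal["responder", "nonresponder"],
           Literal["clinically_meaningful", "reliable", "none"]]:
    """Responder status from the baseline-to-final PCL-5 drop.

    Responder iff drop strictly exceeds ``reliable_thresh`` (a drop of
    exactly 5 is a nonresponder); the tier upgrades to clinically
    meaningful when the drop strictly exceeds ``meaningful_thresh``.
    """
    drop = baseline - final
    if drop > meaningful_thresh:
        return "responder", "clinically_meaningful"
    if drop > reliable_thresh:
        return "responder", "reliable"
    return "nonresponder", "none"


_HAMA_BANDS = ((0, 7, "minimal"), (8, 14, "mild"), (15, 23, "moderate"))
_HAMD_BANDS = ((0, 7, "normal"), (8, 16, "mild"), (17, 23, "moderate"))


def severity_band(instrument: Literal["HAMA", "HAMD"], total: int) -> str:
    """Conventional severity band for a HAM-A or HAM-D total.

    A total of 24 sits in a gap between the published "moderate" range and
    the "greater than 24 = severe" phrasing for both scales; it is assigned
    to severe (documented choice).
    """
    if total < 0:
        raise ValueError("score totals are non-negative")
    bands = {"HAMA": _HAMA_BANDS, "HAMD": _HAMD_BANDS}.get(instrument)
    if bands is None:
        raise ValueError(f"unknown instrument {instrument!r}")
    for lo, hi, label in bands:
        if lo <= total <= hi:
            return label
    return "severe"
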