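"""Personalized stimulation planning from weekly alpha-band parameters.

The planning rule implemented here is the disclosed part of the protocol:
the subject's *intrinsic* alpha frequency is taken from the occipital
leads (visual cortical frequency tends to be preserved even with
psychopathology), every lead whose alpha center frequency deviates from
the intrinsic frequency by more than a threshold is selected for
stimulation *at* the intrinsic frequency, and the session parameters ramp
over the planned course: intensity 25 -> 60 %MT, inter-train interval
30 -> 10 s, 10-15 s trains, ~40 min sessions.

The clinical-response feedback rule is deliberately conservative and is
isolated behind ``ramp_hold_strategy`` so alternatives can be substituted:
if the PCL-5 total rose by more than 5 points since the previous week the
intensity/inter-train ramp is held for one week instead of advancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np

from .eeg_io import Montage, region_leads, standard_montage
from .spectral import ALPHA_BAND, AlphaPeak

__all__ = [
    "TreatmentPlan",
    "intrinsic_frequency",
    "select_targets",
    "session_schedule",
    "make_plan",
    "weekly_update",
]

INTENSITY_RANGE = (25.0, 60.0)   # percent of resting motor threshold
INTERTRAIN_RANGE = (30.0, 10.0)  # seconds, start -> end of course
TRAIN_S_DEFAULT = 12.0           # midpoint of the 10-15 s train range
SESSION_MIN = 40.0


@dataclass
class TreatmentPlan:
    """One week's stimulation plan plus its audit trail."""

    week: int
    intrinsic_freq: float
    targets: tuple[tuple[str, float], ...]
    intensity_pct_mt: float
    train_s: float
    intertrain_s: float
    session_min: float
    ramp_week: int
    n_weeks_planned: int
    pcl5_total: int | None = None
    flags: tuple[str, ...] = ()
    audit: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (ALPHA_BAND[0] <= self.intrinsic_freq <= ALPHA_BAND[1]):
            raise ValueError(f"intrinsic frequency {self.intrinsic_freq} outside 8-13 Hz")
        for lead, f in self.targets:
            if f != self.intrinsic_freq:
                raise ValueError(
                    f"target {lead} assigned {f} Hz != intrinsic {self.intrinsic_freq} Hz"
                )
        if not (INTENSITY_RANGE[0] <= self.intensity_pct_mt <= INTENSITY_RANGE[1]):
            raise ValueError(f"intensity {self.intensity_pct_mt} outside 25-60 %MT")
        if not (10.0 <= self.train_s <= 15.0):
            raise ValueError(f"train length {self.train_s} outside 10-15 s")
        if not (10.0 <= self.intertrain_s <= 30.0):
            raise ValueError(f"inter-train interval {self.intertrain_s} outside 10-30 s")

    def to_dict(self) -> dict:
        return asdict(self)

    def session_sheet(self) -> str:
        lines = [
            f"PrTMS session sheet - week {self.week}",
            f"  intrinsic alpha frequency : {self.intrinsic_freq:.2f} Hz",
            f"  stimulation intensity     : {self.intensity_pct_mt:.0f} %MT",
            f"  train / inter-train       : {self.train_s:.0f} s / {self.intertrain_s:.0f} s",
            f"  session duration          : {self.session_min:.0f} min",
            f"  targets ({len(self.targets)}):",
        ]
        for lead, f in self.targets:
            lines.append(f"    {lead:<4s} @ {f:.2f} Hz")
        for fl in self.flags:
            lines.append(f"  flag: {fl}")
        return "\n".join(lines)


def intrinsic_frequency(
    peaks: Mapping[str, AlphaPeak], montage: Montage | None = None
) -> float:
    """Amplitude-weighted mean occipital alpha center frequency, clamped to 8-13 Hz."""
    montage = montage or standard_montage()
    occ = region_leads(montage, "occipital")
    missing = [l for l in occ if l not in peaks]
    if missing:
        raise ValueError(f"occipital leads without an alpha peak: {missing}")
    centers = np.array([peaks[l].center_freq for l in occ])
    amps = np.array([peaks[l].amplitude for l in occ])
    if amps.sum() <= 0:
        f = float(centers.mean())
    else:
        f = float(np.average(centers, weights=amps))
    return float(np.clip(f, *ALPHA_BAND))


def select_targets(
    peaks: Mapping[str, AlphaPeak],
    intrinsic: float,
    deviation_thresh: float = 0.5,
    montage: Montage | None = None,
) -> tuple[tuple[str, float], ...]:
    """Leads deviating from the intrinsic frequency by more than the threshold.

    Each selected lead is stimulated at the intrinsic frequency.  Occipital
    leads are never targeted: they define the reference.
    """
    if not (ALPHA_BAND[0] <= intrinsic <= ALPHA_BAND[1]):
        raise ValueError(f"intrinsic frequency {intrinsic} outside 8-13 Hz")
    montage = montage or standard_montage()
    occ = set(region_leads(montage, "occipital"))
    out = []
    for lead in montage.leads:
        if lead in occ or lead not in peaks:
            continue
        if abs(peaks[lead].center_freq - intrinsic) > deviation_thresh:
            out.append((lead, intrinsic))
    return tuple(out)


def session_schedule(week: int, n_weeks_planned: int = 6) -> dict[str, float]:
    """Ramped session parameters for ramp position *week* of the planned course."""
    if not (0 <= week < n_weeks_planned):
        raise ValueError(f"week {week} out of range [0, {n_weeks_planned})")
    frac = week / (n_weeks_planned - 1) if n_weeks_planned > 1 else 1.0
    intensity = INTENSITY_RANGE[0] + frac * (INTENSITY_RANGE[1] - INTENSITY_RANGE[0])
    intertrain = INTERTRAIN_RANGE[0] + frac * (INTERTRAIN_RANGE[1] - INTERTRAIN_RANGE[0])
    return {
        "intensity_pct_mt": float(intensity),
        "train_s": TRAIN_S_DEFAULT,
        "intertrain_s": float(intertrain),
        "session_min": SESSION_MIN,
    }


def make_plan(
    peaks: Mapping[str, AlphaPeak],
    week: int = 0,
    n_weeks_planned: int = 6,
    deviation_thresh: float = 0.5,
    montage: Montage | None = None,
    pcl5_total: int | None = None,
    ramp_week: int | None = None,
    flags: Sequence[str] = (),
    audit: Sequence[str] = (),
) -> TreatmentPlan:
    """Build a full plan for one week from per-lead alpha peaks."""
    montage = montage or standard_montage()
    intrinsic = intrinsic_frequency(peaks, montage)
    targets = select_targets(peaks, intrinsic, deviation_thresh, montage)
    rw = week if ramp_week is None else ramp_week
    rw = min(rw, n_weeks_planned - 1)
    sched = session_schedule(rw, n_weeks_planned)
    return TreatmentPlan(
        week=week, intrinsic_freq=intrinsic, targets=targets,
        ramp_week=rw, n_weeks_planned=n_weeks_planned,
        pcl5_total=pcl5_total, flags=tuple(flags), audit=tuple(audit),
        **sched,
    )


def ramp_hold_strategy(prev_pcl5: int | None, new_pcl5: int | None,
                       worsen_thresh: int = 5) -> bool:
    """True when the ramp should be held: PCL-5 rose by more than the threshold."""
    if prev_pcl5 is None or new_pcl5 is None:
        return False
    return (new_pcl5 - prev_pcl5) > worsen_thresh


def weekly_update(
    prev: TreatmentPlan,
    new_peaks: Mapping[str, AlphaPeak],
    new_scores: Mapping[str, int] | None = None,
    deviation_thresh: float = 0.5,
    montage: Montage | None = None,
    hold_strategy: Callable[[int | None, int | None], bool] = ramp_hold_strategy,
) -> TreatmentPlan:
    """Advance the plan one week from fresh EEG features and scores.

    The intrinsic frequency and target set are recomputed from the new
    peaks.  The intensity/inter-train ramp normally advances one step; the
    hold strategy (default: PCL-5 worsened by >5 points) freezes it for a
    week.  Missing scores update the plan from EEG only, flagged.
    """
    montage = montage or standard_montage()
    flags: list[str] = []
    audit = list(prev.audit)
    new_pcl5: int | None = None
    if new_scores is None or "PCL5" not in new_scores:
        flags.append("scores_missing")
        audit.append(f"week {prev.week + 1}: no scores; EEG-only update")
    else:
        new_pcl5 = int(new_scores["PCL5"])
        if prev.pcl5_total is not None:
            audit.append(
                f"week {prev.week + 1}: PCL-5 {prev.pcl5_total} -> {new_pcl5} "
                f"(delta {new_pcl5 - prev.pcl5_total:+d})"
            )
    hold = hold_strategy(prev.pcl5_total, new_pcl5)
    ramp_week = prev.ramp_week if hold else min(prev.ramp_week + 1,
                                                prev.n_weeks_planned - 1)
    if hold:
        flags.append("ramp_held")
        audit.append(f"week {prev.week + 1}: symptom worsening; ramp held at "
                     f"step {ramp_week}")
    return make_plan(
        new_peaks, week=prev.week + 1, n_weeks_planned=prev.n_weeks_planned,
        deviation_thresh=deviation_thresh, montage=montage,
        pcl5_total=new_pcl5 if new_pcl5 is not None else prev.pcl5_total,
        ramp_week=ramp_week, flags=flags, audit=audit,
    )
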