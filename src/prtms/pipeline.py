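"""End-to-end study analysis: weekly feature extraction, responder
classification, and cohort statistics, assembled into a serializable
report.

The pipeline consumes either simulated subjects (:mod:`prtms.synthetic`)
or a directory of per-subject weekly EEG files plus a scores table, and
runs spectral parametrization -> aperiodic fitting -> psychometric
classification -> group statistics.  Every exclusion and filter decision
is logged; the resolved configuration is embedded in the report for
provenance.

Directory layout for ``run_study``::

    input_dir/
      scores.csv              # subject_id, instrument, week, total
      eeg/<subject_id>/week_<w>.csv   (or .edf)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .aperiodic import fit_aperiodic
from .eeg_io import EEGRecording, Montage, read_eeg, region_leads, standard_montage
from .group_stats import (
    fisher_exact_2x2,
    one_sample_t,
    paired_t,
    rm_anova,
    sign_test_binned,
    summarize_cohort,
    threshold_exceedance,
)
from .psychometrics import PCL5_CUTOFF, ScoreSeries, classify_responder
from .spectral import (
    alpha_fwhm,
    alpha_peak,
    band_mean_amplitude,
    peaks_by_lead,
    region_average_spectrum,
    welch_psd,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "SubjectInput",
    "DiskSubject",
    "WeekFeatures",
    "extract_week_features",
    "filter_eligible",
    "analyze_cohort",
    "run_study",
    "write_report",
]

log = logging.getLogger("prtms.pipeline")

REGIONS = ("frontal", "central", "parietal", "occipital")


@dataclass(frozen=True)
class StudyConfig:
    """Resolved analysis configuration; every default named here is tunable."""

    segment_s: float = 10.0
    overlap_frac: float = 0.5
    clip_uv: float = 200.0
    deviation_thresh: float = 0.5
    bin_width: float = 0.5
    pcl5_cutoff: int = PCL5_CUTOFF
    n_weeks: int = 6
    week4: int = 4
    va_active_n: int = 62
    va_sham_n: int = 63

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class SubjectInput(Protocol):
    """Duck type the pipeline consumes (satisfied by synthetic subjects)."""

    @property
    def subject_id(self) -> str: ...
    @property
    def weeks(self) -> list[int]: ...
    @property
    def scores(self) -> dict[str, ScoreSeries]: ...
    def eeg(self, week: int) -> EEGRecording: ...


@dataclass
class DiskSubject:
    """A subject loaded from the documented directory layout."""

    subject_id: str
    scores: dict[str, ScoreSeries]
    eeg_paths: dict[int, Path]

    @property
    def weeks(self) -> list[int]:
        return sorted(self.eeg_paths)

    def eeg(self, week: int) -> EEGRecording:
        return read_eeg(self.eeg_paths[week])


@dataclass
class WeekFeatures:
    """EEG-derived features for one subject-week."""

    week: int
    region_center: dict[str, float]        # alpha center of region-avg spectrum
    lead_centers: dict[str, float]
    frontal_slope: float
    frontal_fwhm: float                    # FWHM of the frontal-average spectrum
    frontal_amp: float                     # mean alpha-band PSD, frontal leads
    cortex_amp: float                      # mean alpha-band PSD, all leads
    n_segments: int


def extract_week_features(
    rec: EEGRecording, week: int, config: StudyConfig,
    montage: Montage | None = None,
) -> WeekFeatures:
    """Spectral + aperiodic features for one recording."""
    montage = montage or standard_montage()
    spec = welch_psd(rec, segment_s=config.segment_s,
                     overlap_frac=config.overlap_frac, clip_uv=config.clip_uv)
    peaks = peaks_by_lead(spec)
    region_center = {}
    for region in REGIONS:
        avg = region_average_spectrum(spec, region_leads(montage, region),
                                      label=region)
        region_center[region] = alpha_peak(avg, region).center_freq
    frontal = region_leads(montage, "frontal")
    frontal_avg = region_average_spectrum(spec, frontal, label="frontal")
    fit = fit_aperiodic(frontal_avg, method="robust")
    # FWHM on the 7-lead frontal average: single-lead Welch noise biases the
    # crossing search low, the averaged spectrum does not
    frontal_width = alpha_fwhm(frontal_avg, "frontal", baseline=fit)
    frontal_amp, _ = band_mean_amplitude(spec, frontal)
    cortex_amp, _ = band_mean_amplitude(spec, None)
    return WeekFeatures(
        week=week,
        region_center=region_center,
        lead_centers={l: p.center_freq for l, p in peaks.items()},
        frontal_slope=fit.slope,
        frontal_fwhm=frontal_width,
        frontal_amp=frontal_amp,
        cortex_amp=cortex_amp,
        n_segments=spec.n_segments,
    )


def filter_eligible(
    subjects: Sequence[SubjectInput], cutoff: int = PCL5_CUTOFF
) -> tuple[list[SubjectInput], list[dict]]:
    """Keep subjects with baseline PCL-5 >= cutoff; log each exclusion."""
    eligible, exclusions = [], []
    for s in subjects:
        pcl5 = s.scores.get("PCL5")
        if pcl5 is None:
            exclusions.append({"subject_id": s.subject_id,
                               "reason": "no baseline PCL-5"})
            log.warning("excluding %s: no baseline PCL-5", s.subject_id)
            continue
        if pcl5.baseline < cutoff:
            exclusions.append({
                "subject_id": s.subject_id,
                "reason": f"baseline PCL-5 {pcl5.baseline} < {cutoff}",
            })
            log.warning("excluding %s: baseline %d below cutoff %d",
                        s.subject_id, pcl5.baseline, cutoff)
            continue
        eligible.append(s)
    return eligible, exclusions


@dataclass
class StudyReport:
    """Aggregated study outputs; serializes losslessly to JSON."""

    config: dict
    n_input: int
    n_eligible: int
    exclusions: list[dict]
    responders: dict
    pcl5_summary: list[dict]
    cfb_tests: dict
    ham_tests: dict
    region_trajectories: dict      # group -> region -> [weekly means]
    sign_tests: dict
    rm_anova_center: dict | None
    fwhm: dict
    amplitude: dict
    aperiodic: dict
    exceedance: dict

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent,
                          sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))


def _subject_features(
    subjects: Sequence[SubjectInput], config: StudyConfig
) -> dict[str, dict[int, WeekFeatures]]:
    feats: dict[str, dict[int, WeekFeatures]] = {}
    for s in subjects:
        per_week: dict[int, WeekFeatures] = {}
        for w in s.weeks:
            try:
                per_week[w] = extract_week_features(s.eeg(w), w, config)
            except ValueError as exc:
                log.warning("%s week %d skipped: %s", s.subject_id, w, exc)
        feats[s.subject_id] = per_week
        log.info("extracted %d weeks for %s", len(per_week), s.subject_id)
    return feats


def _maybe(test_fn, *args, **kwargs):
    try:
        return test_fn(*args, **kwargs).to_dict()
    except (ValueError, KeyError) as exc:
        return {"error": str(exc)}


def analyze_cohort(
    subjects: Sequence[SubjectInput],
    config: StudyConfig | None = None,
    extract_eeg: bool = True,
) -> StudyReport:
    """Run the full analysis over in-memory subjects.

    ``extract_eeg=False`` restricts the report to the psychometric half
    (useful for very large score-only cohorts).
    """
    config = config or StudyConfig()
    if not subjects:
        raise ValueError("empty cohort")
    eligible, exclusions = filter_eligible(list(subjects), config.pcl5_cutoff)
    if not eligible:
        raise ValueError("no eligible subjects after baseline screening")

    # --- psychometrics ----------------------------------------------------
    pcl5 = [s.scores["PCL5"] for s in eligible]
    groups: dict[str, str] = {}
    tiers: dict[str, str] = {}
    for s in eligible:
        status, tier = classify_responder(s.scores["PCL5"].baseline,
                                          s.scores["PCL5"].final)
        groups[s.subject_id] = status
        tiers[s.subject_id] = tier
    n_resp = sum(1 for g in groups.values() if g == "responder")

    week4_split = {
        "below_32": sum(1 for p in pcl5
                        if config.week4 in p.totals and p.at(config.week4) < 32),
        "at_or_above_32": sum(1 for p in pcl5
                              if config.week4 in p.totals
                              and p.at(config.week4) >= 32),
    }

    summary = summarize_cohort(pcl5, list(range(config.n_weeks + 1)))
    cfb_week4 = [p.at(config.week4) - p.baseline for p in pcl5
                 if config.week4 in p.totals]
    cfb_final = [p.final - p.baseline for p in pcl5]
    cfb_tests = {
        "week4": _maybe(one_sample_t, cfb_week4, name="CFB t-test, week 4"),
        "final": _maybe(one_sample_t, cfb_final, name="CFB t-test, final"),
    }

    ham_tests: dict[str, dict] = {}
    for inst in ("HAMA", "HAMD"):
        ham_tests[inst] = {}
        for grp in ("responder", "nonresponder"):
            pre, post = [], []
            for s in eligible:
                if groups[s.subject_id] != grp or inst not in s.scores:
                    continue
                series = s.scores[inst]
                if config.n_weeks in series.totals:
                    pre.append(series.baseline)
                    post.append(series.at(config.n_weeks))
            ham_tests[inst][grp] = _maybe(
                paired_t, pre, post, name=f"{inst} paired t, {grp}")

    drops = [p.baseline - p.final for p in pcl5]
    exceed = threshold_exceedance(drops, thresholds=(5, 10))
    exceedance = {
        "prtms_pct": {str(int(t)): 100.0 * v for t, v in exceed.items()},
        "va_reference_pct": {
            arm: {str(t): v for t, v in d.items()}
            for arm, d in reference.VA_EXCEEDANCE_PCT.items()
        },
        "fisher_vs_va": {},
    }
    for arm, arm_n in (("active", config.va_active_n),
                       ("sham", config.va_sham_n)):
        for thr in (5, 10):
            ours = int(round(exceed[float(thr)] * len(drops)))
            theirs = int(round(reference.VA_EXCEEDANCE_PCT[arm][thr] / 100.0
                               * arm_n))
            table = [[ours, len(drops) - ours], [theirs, arm_n - theirs]]
            exceedance["fisher_vs_va"][f"{arm}_gt{thr}"] = \
                fisher_exact_2x2(table).to_dict()

    responders = {
        "n": len(eligible),
        "n_responders": n_resp,
        "n_nonresponders": len(eligible) - n_resp,
        "responder_pct": 100.0 * n_resp / len(eligible),
        "tiers": {
            "clinically_meaningful": sum(
                1 for t in tiers.values() if t == "clinically_meaningful"),
            "reliable": sum(1 for t in tiers.values() if t == "reliable"),
            "none": sum(1 for t in tiers.values() if t == "none"),
        },
        "week4_score_split": week4_split,
    }

    # --- EEG features -----------------------------------------------------
    region_traj: dict = {}
    sign_tests: dict = {}
    anova_center = None
    fwhm_block: dict = {}
    amp_block: dict = {}
    aper_block: dict = {}

    if extract_eeg:
        feats = _subject_features(eligible, config)

        for grp in ("responder", "nonresponder"):
            ids = [sid for sid, g in groups.items() if g == grp]
            region_traj[grp] = {}
            for region in REGIONS:
                weekly = []
                for w in range(config.n_weeks + 1):
                    vals = [feats[sid][w].region_center[region]
                            for sid in ids if w in feats[sid]]
                    weekly.append(float(np.mean(vals)) if vals else None)
                region_traj[grp][region] = weekly

            pre_f, post_f = [], []
            pre_slope, post_slope = [], []
            pre_w, post_w = [], []
            pre_af, post_af = [], []
            pre_ac, post_ac = [], []
            frontal = region_leads(standard_montage(), "frontal")
            for sid in ids:
                if not feats[sid]:
                    continue
                w0 = min(feats[sid])
                wl = max(feats[sid])
                if wl == w0:
                    continue
                f0, fl = feats[sid][w0], feats[sid][wl]
                pre_f.extend(f0.lead_centers[l] for l in frontal)
                post_f.extend(fl.lead_centers[l] for l in frontal)
                pre_slope.append(f0.frontal_slope)
                post_slope.append(fl.frontal_slope)
                if np.isfinite(f0.frontal_fwhm) and np.isfinite(fl.frontal_fwhm):
                    pre_w.append(f0.frontal_fwhm)
                    post_w.append(fl.frontal_fwhm)
                pre_af.append(f0.frontal_amp)
                post_af.append(fl.frontal_amp)
                pre_ac.append(f0.cortex_amp)
                post_ac.append(fl.cortex_amp)

            sign_tests[grp] = _maybe(
                sign_test_binned, pre_f, post_f, bin_width=config.bin_width)
            fwhm_block[grp] = {
                "pre_mean": float(np.mean(pre_w)) if pre_w else None,
                "post_mean": float(np.mean(post_w)) if post_w else None,
                "paired_t": _maybe(paired_t, pre_w, post_w,
                                   name=f"FWHM paired t, {grp}"),
            }
            amp_block[grp] = {
                "frontal_pre_mean": float(np.mean(pre_af)) if pre_af else None,
                "frontal_post_mean": float(np.mean(post_af)) if post_af else None,
                "cortex_pre_mean": float(np.mean(pre_ac)) if pre_ac else None,
                "cortex_post_mean": float(np.mean(post_ac)) if post_ac else None,
                "frontal_paired_t": _maybe(paired_t, pre_af, post_af,
                                           name=f"frontal amp paired t, {grp}"),
            }
            aper_block[grp] = {
                "pre_mean_slope": float(np.mean(pre_slope)) if pre_slope else None,
                "post_mean_slope": float(np.mean(post_slope)) if post_slope else None,
                "paired_t": _maybe(paired_t, pre_slope, post_slope,
                                   name=f"aperiodic slope paired t, {grp}"),
            }

        # mixed ANOVA on whole-cortex mean center frequency, complete cases
        complete_ids = [sid for sid in feats
                        if all(w in feats[sid] for w in range(config.n_weeks + 1))]
        glabels = [groups[sid] for sid in complete_ids]
        if len(set(glabels)) == 2 and all(
                glabels.count(g) >= 2 for g in set(glabels)):
            mat = np.array([
                [float(np.mean(list(feats[sid][w].region_center.values())))
                 for w in range(config.n_weeks + 1)]
                for sid in complete_ids
            ])
            anova_center = rm_anova(mat, glabels).to_dict()
        else:
            anova_center = {"error": "need >=2 complete subjects per group"}

    return StudyReport(
        config=config.to_dict(),
        n_input=len(subjects),
        n_eligible=len(eligible),
        exclusions=exclusions,
        responders=responders,
        pcl5_summary=summary.drop(columns=["flags"]).to_dict("records")
        if not summary.empty else [],
        cfb_tests=cfb_tests,
        ham_tests=ham_tests,
        region_trajectories=region_traj,
        sign_tests=sign_tests,
        rm_anova_center=anova_center,
        fwhm=fwhm_block,
        amplitude=amp_block,
        aperiodic=aper_block,
        exceedance=exceedance,
    )


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------

def load_subjects(input_dir: str | Path) -> list[DiskSubject]:
    """Load subjects from the documented directory layout."""
    input_dir = Path(input_dir)
    scores_path = input_dir / "scores.csv"
    if not scores_path.exists():
        raise FileNotFoundError(f"{scores_path} not found")
    table = pd.read_csv(scores_path)
    required = {"subject_id", "instrument", "week", "total"}
    if not required.issubset(table.columns):
        raise ValueError(f"scores.csv must have columns {sorted(required)}")
    subjects: dict[str, dict[str, dict[int, int]]] = {}
    for row in table.itertuples(index=False):
        subjects.setdefault(str(row.subject_id), {}).setdefault(
            str(row.instrument), {})[int(row.week)] = int(row.total)

    out = []
    for sid in sorted(subjects):
        series = {
            inst: ScoreSeries(subject_id=sid, instrument=inst, totals=totals)
            for inst, totals in subjects[sid].items() if 0 in totals
        }
        eeg_dir = input_dir / "eeg" / sid
        paths: dict[int, Path] = {}
        if eeg_dir.is_dir():
            for p in sorted(eeg_dir.glob("week_*")):
                if p.suffix.lower() in (".csv", ".edf"):
                    paths[int(p.stem.split("_")[1])] = p
        out.append(DiskSubject(subject_id=sid, scores=series, eeg_paths=paths))
    if not out:
        raise ValueError(f"no subjects found under {input_dir}")
    return out


def run_study(input_dir: str | Path,
              config: StudyConfig | None = None) -> StudyReport:
    """Load the directory layout and run the full analysis."""
    subjects = load_subjects(input_dir)
    has_eeg = any(s.eeg_paths for s in subjects)
    return analyze_cohort(subjects, config=config, extract_eeg=has_eeg)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write report.json plus figure-ready CSV side tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    if report.pcl5_summary:
        pd.DataFrame(report.pcl5_summary).to_csv(
            outdir / "pcl5_summary.csv", index=False)
    rows = []
    for grp, regions in report.region_trajectories.items():
        for region, weekly in regions.items():
            for w, v in enumerate(weekly):
                rows.append({"group": grp, "region": region, "week": w,
                             "mean_center_freq_hz": v})
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "region_trajectories.csv",
                                  index=False)
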