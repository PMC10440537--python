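"""Recovery and calibration studies at the study's reported operating points.

Each function regenerates synthetic data at a stated operating point
(aperiodic exponent, post-treatment alpha center, baseline score
distribution), runs the corresponding pipeline stage from scratch, and
returns the measured quantity.  They are the backbone of the package's
self-checks and of ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .aperiodic import fit_aperiodic
from .eeg_io import region_leads, standard_montage
from .psychometrics import classify_responder
from .spectral import alpha_peak, region_average_spectrum, welch_psd
from .synthetic import (
    CohortParams,
    SubjectParams,
    _key_to_int,
    stratified_normal,
    stream_rng,
    synth_cohort,
    synth_eeg,
    synth_spectrum,
)

__all__ = [
    "aperiodic_slope_recovery",
    "alpha_center_recovery",
    "cohort_calibration",
]

REGIONS = ("frontal", "central", "parietal", "occipital")


def aperiodic_slope_recovery(
    exponent: float,
    n_seeds: int = 50,
    seed: int = 0,
    peak_center: float = 9.6,
    peak_rel_amp: float = 2.0,
    peak_sigma: float = 0.6,
    noise_sigma: float = 0.05,
) -> dict:
    """Mean robust slope over seeded synthetic frontal-average spectra.

    Spectra are drawn directly on the canonical 2-20 Hz grid: a power law
    of the given exponent plus a Gaussian alpha peak (amplitude
    ``peak_rel_amp`` times the aperiodic power at 10 Hz) under
    multiplicative log-normal noise; each is fitted with the robust
    estimator.
    """
    slopes = []
    for i in range(1, n_seeds + 1):
        spec = synth_spectrum(
            exponent, seed=_key_to_int((seed, "slope", exponent, i)),
            peak_center=peak_center, peak_rel_amp=peak_rel_amp,
            peak_sigma=peak_sigma, noise_sigma=noise_sigma,
        )
        slopes.append(fit_aperiodic(spec, method="robust").slope)
    return {
        "mean_slope": float(np.mean(slopes)),
        "sd_slope": float(np.std(slopes, ddof=1)),
        "n": n_seeds,
    }


def alpha_center_recovery(
    n_subjects: int = 20,
    seed: int = 11,
    center: float = 9.6,
    jitter_sd: float = 0.2,
    duration_s: float = 240.0,
    fs: float = 250.0,
) -> dict:
    """Grand mean region-average alpha center for a post-treatment cohort.

    Subjects' week-6 per-region alpha centers sit at ``center`` with
    ``jitter_sd`` Hz of between-subject spread (stratified normal deviates,
    so the generating grand mean is the nominal value at any n); the full
    spectral stage (time-series synthesis -> Welch -> region-average peak)
    is then run and the estimated centers averaged across the four regions
    and all subjects.
    """
    montage = standard_montage()
    rng = stream_rng(seed, "alpha-recovery")
    jitter = stratified_normal(n_subjects, jitter_sd, rng)
    centers = []
    for i in range(n_subjects):
        c = float(np.clip(center + jitter[i], 8.0, 13.0))
        params = SubjectParams(
            subject_id=f"A{i:03d}", group="responder", intrinsic_freq=c,
            lead_deviations=(0.0,) * 19,
            exponent_pre=0.61, exponent_post=0.95,
        ).channel_params(6)  # week-6 (post-treatment) operating point
        rec = synth_eeg(params, duration_s=duration_s, fs=fs,
                        seed=_key_to_int((seed, "alpha", i)))
        spec = welch_psd(rec)
        for region in REGIONS:
            avg = region_average_spectrum(spec, region_leads(montage, region),
                                          label=region)
            centers.append(alpha_peak(avg, region).center_freq)
    return {
        "grand_mean_hz": float(np.mean(centers)),
        "n": n_subjects,
        "n_region_estimates": len(centers),
    }


def cohort_calibration(n_subjects: int = 10000, seed: int = 42) -> dict:
    """Baseline-distribution and responder-fraction check on a default cohort.

    Generates a full default cohort, then measures the baseline PCL-5
    sample moments and the percentage classified as responders by the
    >5-point-drop rule applied to the simulated baseline and final
    (last-observed) totals.
    """
    cohort = synth_cohort(CohortParams(n_subjects=n_subjects, seed=seed))
    baselines = np.array([r.baseline_pcl5 for r in cohort], dtype=float)
    n_resp = sum(
        1 for r in cohort
        if classify_responder(r.baseline_pcl5, r.final_pcl5)[0] == "responder"
    )
    return {
        "baseline_mean": float(baselines.mean()),
        "baseline_sd": float(baselines.std(ddof=1)),
        "baseline_min": float(baselines.min()),
        "responder_pct": 100.0 * n_resp / n_subjects,
        "n": n_subjects,
    }
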