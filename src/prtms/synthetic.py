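"""Synthetic cohort generator: multi-channel resting EEG plus weekly
symptom trajectories with the statistical structure the analysis assumes.

Spectral model
--------------
Each lead's expected power spectral density is an aperiodic power law plus
a Gaussian alpha peak::

    S(f) = 10**offset * f**(-exponent) + amp * exp(-(f - center)**2 / (2 sigma**2))

Time series are realized by inverse-FFT spectral shaping of seeded complex
Gaussian noise, which makes S(f) the exact expectation of the Welch
estimate the pipeline computes — the estimators are probed under a model
whose truth is known bin by bin.

Cohort dynamics (defaults)
--------------------------
Responders (85% of subjects): per-lead alpha centers start deviated above
the subject's intrinsic frequency (pre-treatment region means above 10 Hz)
and converge linearly onto it by week 6 (cohort intrinsic mean 9.6 Hz);
peak width narrows (sigma 1.0 -> 0.6 Hz), peak amplitude rises (x1.6), and
the aperiodic exponent steepens 0.61 -> 0.95.  Nonresponders keep their
deviations, width and amplitude, and their exponent flattens 0.73 -> 0.34.
Baseline PCL-5 totals follow a normal distribution left-truncated at the
screening cutoff 33, numerically calibrated so the post-truncation moments
are 53.3 / 11.46.  Responder scores decline along a ramp that plateaus at
week 4, calibrated so the responder week-4 mean is about 17.7; the
nonresponder change from baseline is near zero.  Weekly dropout follows a
two-phase geometric hazard.

All randomness flows from one root seed through named streams (subject,
week, purpose), so enlarging a cohort never perturbs existing subjects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

from . import reference
from .eeg_io import EEGRecording, LEADS_1020, Montage, standard_montage
from .psychometrics import ScoreSeries
from .spectral import FREQ_GRID, PowerSpectrum

__all__ = [
    "ChannelSpectralParams",
    "SubjectParams",
    "SubjectRecord",
    "CohortParams",
    "spectrum_model",
    "synth_spectrum",
    "synth_eeg",
    "synth_subject",
    "synth_cohort",
    "stream_rng",
    "stratified_normal",
]


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def stream_rng(root_seed: int, *keys: object) -> np.random.Generator:
    """A named random stream derived from the root seed.

    Identical (seed, keys) always give the identical generator, and
    distinct key paths are statistically independent.
    """
    ss = np.random.SeedSequence(int(root_seed) & 0x7FFFFFFF,
                                spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)


def stratified_normal(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """n normal deviates with stratified quantiles (sample mean ~ 0 exactly).

    Used where a small sample must carry the nominal between-subject spread
    without the sample mean itself wandering; the marginal distribution
    matches N(0, sd) to the stratification resolution.
    """
    u = (np.arange(n) + 0.5) / n
    z = special.ndtri(u) * sd
    rng.shuffle(z)
    return z


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpectralParams:
    """Generating spectral parameters for one lead."""

    lead: str
    alpha_center: float            # Hz, in [8, 13]
    alpha_amp: float               # uV^2/Hz above the aperiodic background
    alpha_sigma: float             # Hz, Gaussian width (FWHM = 2.3548 sigma)
    aperiodic_exponent: float      # positive magnitude of the 1/f decay
    aperiodic_offset: float        # log10 power at 1 Hz

    def __post_init__(self) -> None:
        if not (8.0 <= self.alpha_center <= 13.0):
            raise ValueError(f"alpha_center {self.alpha_center} outside 8-13 Hz")
        if self.alpha_amp < 0 or self.alpha_sigma <= 0:
            raise ValueError("alpha_amp must be >= 0 and alpha_sigma > 0")
        if not (0.0 <= self.aperiodic_exponent <= 2.0):
            raise ValueError("aperiodic_exponent outside [0, 2]")


def spectrum_model(freqs: np.ndarray, params: ChannelSpectralParams) -> np.ndarray:
    """Expected PSD (uV^2/Hz) of one lead on *freqs*."""
    f = np.asarray(freqs, dtype=float)
    aper = 10.0 ** params.aperiodic_offset * f ** (-params.aperiodic_exponent)
    peak = params.alpha_amp * np.exp(
        -((f - params.alpha_center) ** 2) / (2.0 * params.alpha_sigma ** 2)
    )
    return aper + peak


def synth_spectrum(
    exponent: float,
    seed: int,
    offset: float | None = None,
    peak_center: float = 9.6,
    peak_rel_amp: float = 2.0,
    peak_sigma: float = 0.6,
    noise_sigma: float = 0.05,
    label: str = "synthetic_avg",
) -> PowerSpectrum:
    """A single-channel spectrum drawn directly on the canonical grid.

    Power-law background with the given exponent, a Gaussian alpha peak
    whose amplitude is ``peak_rel_amp`` times the aperiodic power at 10 Hz,
    and multiplicative log-normal noise of sigma ``noise_sigma`` (natural
    log scale).  This is the fixture for aperiodic-estimator studies where
    the spectrum itself, not the time series, is the object under test.
    """
    if offset is None:
        offset = np.log10(20.0) + exponent  # aperiodic power at 10 Hz = 20
    aper10 = 10.0 ** offset * 10.0 ** (-exponent)
    params = ChannelSpectralParams(
        lead=label, alpha_center=peak_center,
        alpha_amp=peak_rel_amp * aper10, alpha_sigma=peak_sigma,
        aperiodic_exponent=exponent, aperiodic_offset=offset,
    )
    clean = spectrum_model(FREQ_GRID, params)
    rng = stream_rng(seed, "spectrum")
    noisy = clean * np.exp(rng.normal(0.0, noise_sigma, size=clean.size))
    return PowerSpectrum(freqs=FREQ_GRID.copy(), power=noisy[None, :],
                         leads=(label,), fs=0.0, n_segments=1)


def synth_eeg(
    channel_params: Sequence[ChannelSpectralParams],
    duration_s: float = 240.0,
    fs: float = 250.0,
    seed: int = 0,
    montage: Montage | None = None,
    f_floor: float = 0.5,
) -> EEGRecording:
    """Multi-channel EEG whose expected Welch spectrum equals the model.

    Inverse-FFT shaping: for each lead the one-sided spectrum is populated
    with complex Gaussian amplitudes of expected density S(f), with the
    power law held constant below ``f_floor`` Hz to keep the variance
    finite near DC.
    """
    if fs < 40:
        raise ValueError("sampling rate below 40 Hz cannot cover the 2-20 Hz band")
    montage = montage or standard_montage()
    by_lead = {p.lead: p for p in channel_params}
    missing = [l for l in montage.leads if l not in by_lead]
    if missing:
        raise ValueError(f"missing spectral params for leads {missing}")

    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eval = np.maximum(freqs, f_floor)
    rng = stream_rng(seed, "eeg")
    data = np.empty((19, n))
    for i, lead in enumerate(montage.leads):
        s = spectrum_model(f_eval, by_lead[lead])
        amp = np.sqrt(s * fs * n / 2.0)
        z = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        spec = amp * z / np.sqrt(2.0)
        spec[0] = 0.0                      # zero mean
        spec[-1] = spec[-1].real * np.sqrt(2.0)  # Nyquist bin is real
        data[i] = np.fft.irfft(spec, n=n)
    return EEGRecording(data=data, fs=fs, montage=montage)


# ---------------------------------------------------------------------------
# Baseline score distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _calibrate_truncnorm(target_mean: float, target_sd: float,
                         lower: float) -> tuple[float, float]:
    """(mu, sigma) of the untruncated normal whose left-truncation at
    *lower* has the target post-truncation moments."""

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        a = (lower - mu) / sigma
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        mean = mu + sigma * lam
        var = sigma ** 2 * (1.0 + a * lam - lam ** 2)
        return mean, np.sqrt(var)

    def resid(theta):
        m, s = moments(theta[0], abs(theta[1]))
        return [m - target_mean, s - target_sd]

    sol = optimize.fsolve(resid, x0=[target_mean - 2.0, target_sd + 1.0],
                          full_output=False)
    mu, sigma = float(sol[0]), float(abs(sol[1]))
    m, s = moments(mu, sigma)
    if abs(m - target_mean) > 1e-6 or abs(s - target_sd) > 1e-6:
        raise RuntimeError("truncated-normal calibration failed to converge")
    return mu, sigma


def sample_baseline_pcl5(
    rng: np.random.Generator,
    size: int | None = None,
    mean: float = 53.3,
    sd: float = 11.46,
    lower: float = 33.0,
):
    """Baseline PCL-5 draws from the calibrated left-truncated normal."""
    mu, sigma = _calibrate_truncnorm(mean, sd, lower)
    a = (lower - mu) / sigma
    p_lo = stats.norm.cdf(a)
    u = rng.uniform(size=size)
    z = special.ndtri(p_lo + u * (1.0 - p_lo))
    return mu + sigma * z


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _ramp(week: float, plateau_week: float, tau: float = 1.5) -> float:
    """Saturating improvement ramp: steep over the first weeks, 1 at plateau.

    Score gains concentrate in the first treatment week and level off at
    the plateau (week 4 by default), matching the observed trajectory of
    early response followed by a plateauing rate.
    """
    if plateau_week <= 0:
        return 1.0
    w = min(week, plateau_week)
    return float((1.0 - np.exp(-w / tau)) / (1.0 - np.exp(-plateau_week / tau)))


@dataclass(frozen=True)
class SubjectParams:
    """Generating parameters for one subject."""

    subject_id: str
    group: Literal["responder", "nonresponder"]
    intrinsic_freq: float
    lead_deviations: tuple[float, ...]      # per-lead week-0 center offsets, Hz
    exponent_pre: float
    exponent_post: float
    sigma_pre: float = 1.0
    sigma_post: float = 0.6
    rel_amp_pre: float = 2.0
    rel_amp_post: float = 3.2
    aperiodic_offset: float | None = None   # default: power-at-10Hz anchor
    baseline_pcl5: int = 53
    drop_pcl5: float = 0.0                  # total drop at plateau
    baseline_hama: int = 27
    drop_hama: float = 0.0
    baseline_hamd: int = 25
    drop_hamd: float = 0.0
    plateau_week: int = 4
    score_noise_sd: float = 1.5
    n_weeks: int = 6
    dropout_week: int | None = None         # last observed week, None = completed

    def __post_init__(self) -> None:
        if len(self.lead_deviations) != 19:
            raise ValueError("need one deviation per lead (19)")
        if self.group == "responder":
            if self.exponent_post < self.exponent_pre:
                raise ValueError("responder exponent must steepen (increase)")
            if self.sigma_post > self.sigma_pre or self.rel_amp_post < self.rel_amp_pre:
                raise ValueError("responder peaks must narrow and grow")
        elif self.group == "nonresponder":
            if self.exponent_post > self.exponent_pre:
                raise ValueError("nonresponder exponent must flatten (decrease)")
        else:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def last_week(self) -> int:
        w = self.n_weeks if self.dropout_week is None else self.dropout_week
        return min(w, self.n_weeks)

    def channel_params(self, week: int) -> tuple[ChannelSpectralParams, ...]:
        """Per-lead spectral parameters at *week* (0 .. n_weeks)."""
        frac = week / self.n_weeks
        responder = self.group == "responder"
        conv = frac if responder else 0.0           # deviation shrink factor
        sigma = self.sigma_pre + frac * (self.sigma_post - self.sigma_pre) \
            if responder else self.sigma_pre
        rel_amp = self.rel_amp_pre + frac * (self.rel_amp_post - self.rel_amp_pre) \
            if responder else self.rel_amp_pre
        exponent = self.exponent_pre + frac * (self.exponent_post - self.exponent_pre)
        offset = (np.log10(20.0) + exponent if self.aperiodic_offset is None
                  else self.aperiodic_offset)
        out = []
        for lead, dev in zip(LEADS_1020, self.lead_deviations):
            center = float(np.clip(self.intrinsic_freq + dev * (1.0 - conv),
                                   8.0, 13.0))
            aper_c = 10.0 ** offset * center ** (-exponent)
            out.append(ChannelSpectralParams(
                lead=lead, alpha_center=center, alpha_amp=rel_amp * aper_c,
                alpha_sigma=sigma, aperiodic_exponent=exponent,
                aperiodic_offset=offset,
            ))
        return tuple(out)

    def expected_score(self, instrument: str, week: int) -> float:
        base, drop = {
            "PCL5": (self.baseline_pcl5, self.drop_pcl5),
            "HAMA": (self.baseline_hama, self.drop_hama),
            "HAMD": (self.baseline_hamd, self.drop_hamd),
        }[instrument]
        return base - drop * _ramp(week, self.plateau_week)


@dataclass
class SubjectRecord:
    """One simulated subject: weekly scores plus on-demand weekly EEG."""

    params: SubjectParams
    seed: int
    scores: dict[str, ScoreSeries]
    fs: float = 250.0
    duration_s: float = 240.0

    @property
    def subject_id(self) -> str:
        return self.params.subject_id

    @property
    def weeks(self) -> list[int]:
        return list(range(self.params.last_week + 1))

    def eeg(self, week: int) -> EEGRecording:
        """Synthesize (deterministically) this subject's EEG for *week*."""
        if week not in self.weeks:
            raise KeyError(f"{self.subject_id}: week {week} not observed")
        return synth_eeg(
            self.params.channel_params(week), duration_s=self.duration_s,
            fs=self.fs, seed=_key_to_int((self.seed, self.subject_id, week)),
        )

    @property
    def baseline_pcl5(self) -> int:
        return self.scores["PCL5"].baseline

    @property
    def final_pcl5(self) -> int:
        return self.scores["PCL5"].final


_INSTRUMENT_CAP = {"PCL5": 80, "HAMA": 56, "HAMD": 52}


def synth_subject(params: SubjectParams, seed: int,
                  fs: float = 250.0, duration_s: float = 240.0) -> SubjectRecord:
    """Simulate the weekly score series (EEG is synthesized lazily)."""
    scores: dict[str, ScoreSeries] = {}
    for inst in ("PCL5", "HAMA", "HAMD"):
        rng = stream_rng(seed, params.subject_id, "scores", inst)
        totals: dict[int, int] = {}
        for week in range(params.last_week + 1):
            mu = params.expected_score(inst, week)
            noise = 0.0 if week == 0 else rng.normal(0.0, params.score_noise_sd)
            totals[week] = int(np.clip(round(mu + noise), 0, _INSTRUMENT_CAP[inst]))
        scores[inst] = ScoreSeries(subject_id=params.subject_id,
                                   instrument=inst, totals=totals)
    return SubjectRecord(params=params, seed=seed, scores=scores,
                         fs=fs, duration_s=duration_s)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generating parameters (defaults = study conditions)."""

    n_subjects: int
    seed: int = 0
    responder_fraction: float = reference.RESPONDER_FRACTION
    baseline_mean: float = 53.3
    baseline_sd: float = 11.46
    baseline_min: float = 33.0
    intrinsic_mean: float = 9.6
    intrinsic_sd: float = 0.2
    deviation_mean: float = 0.9     # week-0 per-lead upward center offset, Hz
    deviation_sd: float = 0.3
    responder_week4_mean: float = 17.7   # target responder week-4 PCL-5 score
    responder_week4_sd: float = 9.44
    nonresponder_drop_mean: float = 0.5
    nonresponder_drop_sd: float = 1.5
    dropout_hazard_early: float = 0.066  # per week, through the planned course
    dropout_hazard_late: float = 0.122   # per week beyond the planned course
    n_weeks: int = 6
    fs: float = 250.0
    duration_s: float = 240.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction outside [0, 1]")


def _draw_dropout(rng: np.random.Generator, cohort: CohortParams) -> int | None:
    """Last observed week under the two-phase geometric hazard (>= 1)."""
    week = 1
    while True:
        h = (cohort.dropout_hazard_early if week <= cohort.n_weeks
             else cohort.dropout_hazard_late)
        if rng.uniform() < h:
            return week if week < cohort.n_weeks else None
        week += 1
        if week > cohort.n_weeks:
            return None  # completed the simulated course


def synth_cohort(cohort: CohortParams) -> list[SubjectRecord]:
    """Draw a full cohort, reproducibly from the cohort seed.

    Each subject consumes only its own named random streams, so cohorts of
    different sizes share their common prefix subject-for-subject.
    """
    responder_exp = tuple(-s for s in reference.APERIODIC_SLOPES["responder"])
    nonresp_exp = tuple(-s for s in reference.APERIODIC_SLOPES["nonresponder"])
    records: list[SubjectRecord] = []
    for i in range(cohort.n_subjects):
        sid = f"S{i:05d}"
        rng = stream_rng(cohort.seed, sid, "design")
        group = ("responder" if rng.uniform() < cohort.responder_fraction
                 else "nonresponder")
        baseline = float(sample_baseline_pcl5(
            rng, mean=cohort.baseline_mean, sd=cohort.baseline_sd,
            lower=cohort.baseline_min,
        ))
        baseline_i = int(np.clip(round(baseline), cohort.baseline_min, 80))
        intrinsic = float(np.clip(
            rng.normal(cohort.intrinsic_mean, cohort.intrinsic_sd), 8.3, 12.0))
        devs = rng.normal(cohort.deviation_mean, cohort.deviation_sd, size=19)
        devs = tuple(float(d) for d in np.clip(devs, 0.0, 12.9 - intrinsic))

        if group == "responder":
            target = rng.normal(cohort.responder_week4_mean,
                                cohort.responder_week4_sd)
            target = float(np.clip(target, 0.0, baseline_i - 8.0))
            drop = baseline_i - target
            hama_drop = float(np.clip(rng.normal(14.0, 3.0), 4.0, 25.0))
            hamd_drop = float(np.clip(rng.normal(13.0, 3.0), 4.0, 25.0))
            exp_pre, exp_post = responder_exp
            sigma_pre, sigma_post = 1.0, 0.6
            amp_pre, amp_post = 2.0, 3.2
        else:
            drop = float(rng.normal(cohort.nonresponder_drop_mean,
                                    cohort.nonresponder_drop_sd))
            hama_drop = float(rng.normal(0.0, 1.0))
            hamd_drop = float(rng.normal(0.0, 1.0))
            exp_pre, exp_post = nonresp_exp
            sigma_pre = sigma_post = 1.0
            amp_pre = amp_post = 2.0

        params = SubjectParams(
            subject_id=sid, group=group, intrinsic_freq=intrinsic,
            lead_deviations=devs,
            exponent_pre=exp_pre, exponent_post=exp_post,
            sigma_pre=sigma_pre, sigma_post=sigma_post,
            rel_amp_pre=amp_pre, rel_amp_post=amp_post,
            baseline_pcl5=baseline_i, drop_pcl5=drop,
            baseline_hama=int(np.clip(round(rng.normal(27, 4)), 10, 56)),
            drop_hama=hama_drop,
            baseline_hamd=int(np.clip(round(rng.normal(25, 4)), 10, 52)),
            drop_hamd=hamd_drop,
            n_weeks=cohort.n_weeks,
            dropout_week=_draw_dropout(stream_rng(cohort.seed, sid, "dropout"),
                                       cohort),
        )
        records.append(synth_subject(params, seed=cohort.seed,
                                     fs=cohort.fs, duration_s=cohort.duration_s))
    return records
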