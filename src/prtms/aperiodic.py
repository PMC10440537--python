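"""1/f aperiodic component of a region-averaged spectrum.

The broadband background of an EEG power spectrum follows an approximate
power law P(f) ~ C * f**(-a); in log-log coordinates it is a straight line
whose slope (expected negative) indexes the excitation/inhibition balance
of the underlying population.  The line is fitted over the full 2-20 Hz
band by iteratively reweighted least squares with a Tukey bisquare loss, so
oscillatory bins (the alpha peak) are treated as outliers and rejected
rather than biasing the slope.  An ordinary-least-squares variant is kept
as the non-robust baseline.

The bisquare tuning constant defaults to 4.685 (95% Gaussian efficiency);
the residual scale is the normalized median absolute deviation,
re-estimated at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .spectral import PowerSpectrum

__all__ = ["AperiodicFit", "fit_aperiodic", "aperiodic_change"]

_MAD_NORM = 0.6744897501960817  # Phi^{-1}(3/4): MAD -> sigma for a Gaussian


@dataclass
class AperiodicFit:
    """Log-log linear fit of the aperiodic background.

    ``offset`` is the log10 power at 1 Hz (the intercept in log10 f);
    ``slope`` is the log10-power-per-log10-Hz slope, negative for a
    decaying 1/f background.
    """

    offset: float
    slope: float
    inlier_mask: np.ndarray
    method: Literal["robust", "ols"]
    rmse_inliers: float
    converged: bool = True
    many_outliers: bool = False

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        """Model power (linear units) on *freqs*."""
        return 10.0 ** (self.offset + self.slope * np.log10(np.asarray(freqs, float)))

    def to_dict(self) -> dict:
        return {
            "offset": self.offset,
            "slope": self.slope,
            "method": self.method,
            "n_inliers": int(self.inlier_mask.sum()),
            "rmse_inliers": self.rmse_inliers,
            "converged": self.converged,
        }


def _mad_scale(r: np.ndarray) -> float:
    return float(np.median(np.abs(r - np.median(r))) / _MAD_NORM)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return beta


def fit_aperiodic(
    avg_spec: PowerSpectrum,
    method: Literal["robust", "ols"] = "robust",
    tuning: float = 4.685,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AperiodicFit:
    """Fit the aperiodic line to a single-channel spectrum.

    The robust method iterates bisquare-weighted least squares until the
    maximum weight change falls below ``tol`` or ``max_iter`` iterations;
    non-convergence returns the last iterate with ``converged=False``.
    All bins must have strictly positive power (the log must exist).
    """
    if not avg_spec.is_single:
        raise ValueError("fit_aperiodic expects a single-channel (region-averaged) "
                         f"spectrum, got {len(avg_spec.leads)} channels")
    p = avg_spec.power[0]
    if np.any(p <= 0):
        raise ValueError("aperiodic fit requires strictly positive power in every bin")
    x = np.log10(avg_spec.freqs)
    y = np.log10(p)

    beta = _wls(x, y, np.ones_like(x))
    if method == "ols":
        r = y - (beta[0] + beta[1] * x)
        mask = np.ones_like(x, dtype=bool)
        return AperiodicFit(
            offset=float(beta[0]), slope=float(beta[1]), inlier_mask=mask,
            method="ols", rmse_inliers=float(np.sqrt(np.mean(r ** 2))),
        )
    if method != "robust":
        raise ValueError(f"unknown method {method!r}")

    w = np.ones_like(x)
    converged = False
    for _ in range(max_iter):
        r = y - (beta[0] + beta[1] * x)
        s = _mad_scale(r)
        floor = 1e-10 * max(1.0, float(np.median(np.abs(y))))
        if s <= floor:
            # inlier fit is exact to machine noise: bins at machine-level
            # residual are inliers, anything else stays rejected
            w = np.where(np.abs(r) <= max(floor, 1e3 * np.finfo(float).eps),
                         1.0, 0.0)
            converged = True
            break
        u = r / (tuning * s)
        w_new = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
        if w.sum() < 3:  # degenerate: nearly everything rejected
            break
        beta = _wls(x, y, w)

    mask = w > 0
    r = y - (beta[0] + beta[1] * x)
    rmse = float(np.sqrt(np.mean(r[mask] ** 2))) if mask.any() else float("nan")
    return AperiodicFit(
        offset=float(beta[0]), slope=float(beta[1]), inlier_mask=mask,
        method="robust", rmse_inliers=rmse, converged=converged,
        many_outliers=bool((~mask).sum() > mask.size // 2),
    )


def aperiodic_change(
    pre_fit: AperiodicFit, post_fit: AperiodicFit, tol: float = 0.02
) -> tuple[float, Literal["steeper", "flatter", "unchanged"]]:
    """Slope change post - pre with a direction label.

    "steeper" means the background decays faster after treatment (delta
    below -tol); "flatter" the opposite; changes within +/-tol are
    "unchanged".
    """
    if pre_fit.method != post_fit.method:
        raise ValueError("cannot compare fits from different methods "
                         f"({pre_fit.method} vs {post_fit.method})")
    delta = post_fit.slope - pre_fit.slope
    if delta < -tol:
        label: Literal["steeper", "flatter", "unchanged"] = "steeper"
    elif delta > tol:
        label = "flatter"
    else:
        label = "unchanged"
    return float(delta), label
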