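"""Mono-exponential T2 fitting for CPMG-HSQC intensity decays.

Transverse relaxation shortened by micro- to millisecond conformational
exchange is the NMR signature of backbone flexibility on that timescale; a
series of spin-echo (CPMG) spectra at increasing relaxation delays yields a
per-site intensity decay ``I(t) = I0 * exp(-t / T2)``.  The fit is plain
nonlinear least squares (no baseline offset by default, matching how such
decays are conventionally fit; an optional offset term is available) with
an asymptotic 95% confidence interval for T2 from the parameter covariance
and a t-distribution with n - p degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .errors import DimensionError, FitError

__all__ = ["DecayCurve", "T2FitResult", "fit_t2", "CPMG_DELAY_GRID_S"]

#: ten evenly spaced relaxation delays, 15.2 ms to 456 ms
CPMG_DELAY_GRID_S = tuple(np.linspace(0.0152, 0.456, 10))


@dataclass(frozen=True)
class DecayCurve:
    """One site's intensity-vs-delay series."""

    delays: np.ndarray
    intensities: np.ndarray
    site: str = ""
    overlapped: bool = False  # user-marked partially overlapping peak

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, float)
        i = np.asarray(self.intensities, float)
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "intensities", i)
        if d.ndim != 1 or d.shape != i.shape:
            raise DimensionError("delays and intensities must be matching 1D arrays")
        if d.size < 3:
            raise DimensionError(f"need >= 3 delay points to fit a decay, got {d.size}")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise DimensionError("delays must be positive and strictly increasing")


@dataclass
class T2FitResult:
    """Fitted amplitude and T2 with an asymptotic 95% CI (labelled as such)."""

    I0: float
    T2: float
    t2_ci95: tuple[float, float]
    t2_stderr: float
    offset: float
    rms_residual: float
    overlapped: bool


def fit_t2(curve: DecayCurve, offset: bool = False, confidence: float = 0.95) -> T2FitResult:
    """Fit ``I(t) = I0 exp(-t/T2) (+ c)`` by nonlinear least squares.

    The intensities are normalized internally by their maximum so the fit is
    exactly scale-equivariant: scaling the data scales I0 and leaves T2 and
    its CI unchanged.  Initial values come from a log-linear regression.

    Raises ``FitError`` for non-decaying data (best-fit T2 <= 0 or
    divergent) and for all-equal intensities.
    """
    t = curve.delays
    y = curve.intensities
    if np.ptp(y) == 0:
        raise FitError(f"site {curve.site!r}: intensities are all equal; nothing to fit")
    scale = np.max(np.abs(y))
    if scale == 0:
        raise FitError(f"site {curve.site!r}: all intensities are zero")
    yn = y / scale

    n_par = 3 if offset else 2
    if t.size < n_par + 1:
        raise FitError(
            f"site {curve.site!r}: {t.size} points cannot constrain {n_par} parameters"
        )

    # initial values: log-linear regression (exact for noise-free decays)
    # plus a coarse grid on T2 with the amplitude solved linearly; the
    # Levenberg-Marquardt refinement is started from the candidates in order
    # of their residual sum, accepting the first convergent decaying fit --
    # single starts are fragile when the late delays are noise-dominated
    candidates = []
    pos = yn > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(yn[pos]), 1)
        if slope < 0:
            candidates.append((float(np.exp(intercept)), float(-1.0 / slope)))
    for t2_try in np.geomspace(t[0] / 3.0, t[-1] * 10.0, 25):
        e = np.exp(-t / t2_try)
        i0_try = float(e @ yn / (e @ e))
        candidates.append((i0_try, float(t2_try)))
    candidates.sort(key=lambda c0: float(np.sum((yn - c0[0] * np.exp(-t / c0[1])) ** 2)))

    if offset:
        def model(tt, i0, t2, c):
            return i0 * np.exp(-np.clip(tt / t2, -700, 700)) + c
    else:
        def model(tt, i0, t2):
            return i0 * np.exp(-np.clip(tt / t2, -700, 700))

    best = None
    failure = "no admissible starting point"
    for i0_init, t2_init in candidates[:8]:
        p0 = [i0_init, t2_init] + ([0.0] if offset else [])
        try:
            popt, pcov = curve_fit(
                model, t, yn, p0=p0, maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except RuntimeError:
            failure = "optimizer did not converge"
            continue
        i0_c, t2_c = popt[0], popt[1]
        if not np.isfinite(t2_c) or t2_c <= 0 or i0_c <= 0 or t2_c > 1000 * t[-1]:
            failure = f"best fit (I0 = {i0_c * scale:.3g}, T2 = {t2_c:.3g} s) is not a decay"
            continue
        if not np.isfinite(pcov[1, 1]) or pcov[1, 1] < 0:
            failure = "singular fit covariance"
            continue
        sse = float(np.sum((yn - model(t, *popt)) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitError(f"site {curve.site!r}: {failure}")
    popt, pcov, _ = best

    i0, t2 = float(popt[0]), float(popt[1])
    c = popt[2] if offset else 0.0
    resid = yn - model(t, *popt)
    dof = t.size - n_par
    stderr = float(np.sqrt(pcov[1, 1]))
    tcrit = float(t_dist.ppf(0.5 + confidence / 2.0, dof))
    return T2FitResult(
        I0=float(i0 * scale),
        T2=float(t2),
        t2_ci95=(float(t2 - tcrit * stderr), float(t2 + tcrit * stderr)),
        t2_stderr=stderr,
        offset=float(c * scale),
        rms_residual=float(np.sqrt(np.mean(resid**2)) * scale),
        overlapped=curve.overlapped,
    )
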