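"""DSB and ChIP kinetics: broken fractions, Poisson correction, curve fits.

PFGE quantification gives the fraction of chromosomes broken at each
time point.  Because a chromatid can receive more than one break, the
observed broken fraction f understates the mean number of breaks; under
a Poisson model the mean is lambda = -ln(1 - f), the unique rate whose
zero-break probability is 1 - f.

DSB timing is summarized by fitting

    y = a + b * exp{-[log(x + 1) - c]^2 / d^2}

to the broken fraction over time x (hours), with the background a
pinned to the 0-h measurement and (b, c, d) estimated by least squares
(log is the natural logarithm).  The curve peaks at x = e^c - 1 hours.

ChIP time courses of a DSB-promoting protein are reduced to a binding
window: the same unimodal form locates the peak, then logistic curves
fitted separately to the rising and falling slopes give the association
and dissociation times as their half-maximum points; binding duration
is their difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .genome_io import IntegrityError, TimeCourse

__all__ = [
    "KineticFit",
    "BindingWindow",
    "FitError",
    "lognormal_model",
    "dsb_fraction",
    "poisson_correct",
    "fraction_from_mean",
    "fit_dsb_kinetics",
    "time_averaged_dsbs",
    "fit_chip_kinetics",
]


class FitError(RuntimeError):
    """A curve fit failed to converge; the message carries diagnostics."""


def lognormal_model(t, a, b, c, d):
    """a + b * exp{-[log(t + 1) - c]^2 / d^2}, natural log."""
    t = np.asarray(t, dtype=np.float64)
    return a + b * np.exp(-((np.log(t + 1.0) - c) ** 2) / d**2)


@dataclass(frozen=True)
class KineticFit:
    """Fitted unimodal DSB-timing curve.

    ``a`` is the background (fixed to the 0-h value), ``b`` the peak
    height above background, ``c`` the peak position on the log(x+1)
    scale and ``d`` the width (SD equivalent).  ``peak_time_h`` is
    e^c - 1, the time at which the fitted curve is maximal.
    """

    a: float
    b: float
    c: float
    d: float
    rss: float
    converged: bool

    def __post_init__(self):
        if self.b < 0 or self.d <= 0:
            raise IntegrityError("KineticFit requires b >= 0 and d > 0")

    @property
    def peak_time_h(self) -> float:
        return math.exp(self.c) - 1.0

    @property
    def peak_value(self) -> float:
        return self.a + self.b

    def predict(self, t) -> np.ndarray:
        return lognormal_model(t, self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class BindingWindow:
    """Association/dissociation timing of a chromatin-bound protein."""

    peak_time_h: float
    t_assoc_h: float
    t_dissoc_h: float

    def __post_init__(self):
        if not (self.t_assoc_h <= self.peak_time_h <= self.t_dissoc_h):
            raise IntegrityError(
                "binding window must bracket the peak: "
                f"{self.t_assoc_h} <= {self.peak_time_h} <= {self.t_dissoc_h}"
            )

    @property
    def duration_h(self) -> float:
        return self.t_dissoc_h - self.t_assoc_h


def dsb_fraction(broken_signal: float, parental_signal: float) -> float:
    """Broken fraction f = broken / (parental + broken), in [0, 1)."""
    if broken_signal < 0 or parental_signal < 0:
        raise IntegrityError("signals must be non-negative")
    total = broken_signal + parental_signal
    if total == 0:
        raise IntegrityError("both signals are zero; fraction undefined")
    return broken_signal / total


def poisson_correct(f: float) -> float:
    """Mean breaks per chromosome from an observed broken fraction.

    lambda = -ln(1 - f): the Poisson mean whose zero class has
    probability 1 - f.  Monotone increasing and always >= f.
    """
    f = float(f)
    if not 0.0 <= f < 1.0:
        raise IntegrityError(f"broken fraction must be in [0, 1), got {f}")
    return -math.log1p(-f)


def fraction_from_mean(lam: float) -> float:
    """Inverse of :func:`poisson_correct`: f = 1 - exp(-lambda)."""
    if lam < 0:
        raise IntegrityError("mean breaks must be >= 0")
    return -math.expm1(-lam)


_D_STARTS = (0.3, 0.6, 1.2)


def fit_dsb_kinetics(tc: TimeCourse) -> KineticFit:
    """Least-squares fit of the log-normal timing curve to one series.

    Requires >= 4 time points including t = 0; the background ``a`` is
    fixed to the 0-h value and (b, c, d) are optimized from a
    deterministic grid of starts (no randomness).
    """
    if tc.times.size < 4:
        raise IntegrityError("need at least 4 time points")
    if tc.times[0] != 0.0:
        raise IntegrityError("series must include a 0-h point (background)")
    return _fit_lognormal(tc.times, tc.values, float(tc.values[0]), tc.label)


def _fit_lognormal(t: np.ndarray, y: np.ndarray, a: float, label: str) -> KineticFit:
    def resid(p):
        b, c, d = p
        return lognormal_model(t, a, b, c, d) - y

    b0 = max(float(y.max() - a), 1e-8)
    c0 = math.log(float(t[np.argmax(y)]) + 1.0)
    best = None
    for d0 in _D_STARTS:
        for c_start in (c0, c0 + 0.3, max(c0 - 0.3, 1e-3)):
            try:
                res = least_squares(
                    resid,
                    x0=[b0, c_start, d0],
                    bounds=([0.0, -10.0, 1e-6], [np.inf, 10.0, 50.0]),
                    method="trf",
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None or not best[1].success:
        raise FitError(f"log-normal fit failed for {label!r}: no start converged")
    rss, res = best
    b, c, d = res.x
    return KineticFit(a=a, b=float(b), c=float(c), d=float(d),
                      rss=rss, converged=bool(res.success))


def time_averaged_dsbs(tc: TimeCourse, subtract_background: bool = False) -> float:
    """Trapezoidal area under the observed series, in percent-hours.

    With ``subtract_background`` the 0-h value is subtracted from every
    point first (negative excursions are kept as-is; the integral is of
    the observed data, not a fitted curve).
    """
    if len(tc) < 2:
        raise IntegrityError("need at least 2 points for an area")
    y = tc.values - (tc.values[0] if subtract_background else 0.0)
    return float(np.trapezoid(y, tc.times))


def _logistic(t, L, k, t0):
    return L / (1.0 + np.exp(-k * (t - t0)))


def _fit_logistic(t: np.ndarray, y: np.ndarray, rising: bool, label: str) -> float:
    """Fit L / (1 + exp(-+k (t - t0))) and return t0, the half-maximum
    time on the fitted plateau L."""
    sign = 1.0 if rising else -1.0

    def resid(p):
        L, k, t0 = p
        return _logistic(t, L, sign * k, t0) - y

    L0 = max(float(y.max()), 1e-8)
    half = L0 / 2.0
    # first crossing of half-maximum, linearly interpolated, as t0 start
    above = y >= half
    t0_guess = float(t[np.argmax(above)] if above.any() else t[t.size // 2])
    span = max(float(t[-1] - t[0]), 1e-3)
    best = None
    for k0 in (0.5, 2.0, 8.0):
        for t0_start in (t0_guess, t0_guess - 0.25 * span, t0_guess + 0.25 * span):
            try:
                res = least_squares(
                    resid,
                    x0=[L0, k0, t0_start],
                    bounds=(
                        [1e-9, 1e-3, t[0] - 2 * span],
                        [np.inf, 1e3, t[-1] + 2 * span],
                    ),
                    method="trf",
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None or not best[1].success:
        raise FitError(f"logistic fit failed on the {label} slope")
    return float(best[1].x[2])


def fit_chip_kinetics(tc: TimeCourse) -> BindingWindow:
    """Binding window of a ChIP time course.

    Stage 1 fits the unimodal timing curve to all points to locate the
    signal peak.  Stage 2 fits a rising logistic to the points up to and
    including the peak; its half-maximum time is the association time.
    Stage 3 mirrors this on the falling side for the dissociation time.
    Either slope with fewer than 3 points raises :class:`FitError`
    naming the slope.  Half-maximum times landing beyond the peak (a
    degenerate slope) are clipped to the peak time.
    """
    if len(tc) < 6:
        raise IntegrityError("need at least 6 time points for a binding window")
    # background pinned to the earliest sample; a 0-h point is not required
    peak = _fit_lognormal(
        tc.times, tc.values, float(tc.values[0]), tc.label
    ).peak_time_h

    t, y = tc.times, tc.values
    rise_mask = t <= peak
    # always include the sample nearest the peak on each side
    nearest = int(np.argmin(np.abs(t - peak)))
    rise_mask[nearest] = True
    fall_mask = t >= peak
    fall_mask[nearest] = True

    if rise_mask.sum() < 3:
        raise FitError("fewer than 3 points on the rising slope")
    if fall_mask.sum() < 3:
        raise FitError("fewer than 3 points on the falling slope")

    t_assoc = _fit_logistic(t[rise_mask], y[rise_mask], rising=True, label="rising")
    t_dissoc = _fit_logistic(t[fall_mask], y[fall_mask], rising=False, label="falling")
    t_assoc = min(t_assoc, peak)
    t_dissoc = max(t_dissoc, peak)
    return BindingWindow(peak_time_h=peak, t_assoc_h=t_assoc, t_dissoc_h=t_dissoc)
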