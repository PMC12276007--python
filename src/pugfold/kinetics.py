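"""Kinetic and thermodynamic model fitting for pUG folding studies.

Four models are fit by nonlinear least squares (analytic Jacobians,
scipy.optimize.least_squares, ftol/xtol 1e-12, max 10^4 evaluations):

* single-exponential folding, S(t) = S_inf + (S_0 - S_inf) exp(-k t),
  for the CD folding traces (half-lives of minutes);
* mono-exponential HDX decay, I(t) = [I(0) - I(inf)] exp(-k_ex t) + I(inf),
  with the floor I(inf) constrained to 0 by default (no residual imino
  signal after months in D2O);
* biexponential HDX decay,
  I(t) = I0 [f exp(-k_fast t) + (1 - f) exp(-k_slow t)],
  whose fast-phase fraction f ("Ratio fast") is ~50% for chains longer
  than 12 repeats;
* the Boltzmann sigmoid y(T) = A2 + (A1 - A2) / (1 + exp((T - Tm)/dT))
  for thermal melts.

Time-unit conventions follow the measurements: folding traces in minutes,
HDX in hours, melts in degrees C; conversions are explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

LN2 = math.log(2.0)

TIME_UNIT_SECONDS = {"s": 1.0, "min": 60.0, "h": 3600.0, "day": 86400.0}

_LSQ_OPTS = dict(ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=10_000)


class FitError(RuntimeError):
    """Raised when a model cannot be fit to the supplied data."""


# --------------------------------------------------------------------------
# rate / half-life conversions


def halflife_from_rate(k: float) -> float:
    """t_half = ln2 / k, in the time base of k."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return LN2 / k


def rate_from_halflife(t_half: float) -> float:
    """k = ln2 / t_half, in the time base of t_half."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return LN2 / t_half


def convert_time(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a duration between s, min, h, day."""
    return value * TIME_UNIT_SECONDS[from_unit] / TIME_UNIT_SECONDS[to_unit]


def convert_rate(k: float, from_unit: str, to_unit: str) -> float:
    """Convert a first-order rate between per-s, per-min, per-h, per-day."""
    return k * TIME_UNIT_SECONDS[to_unit] / TIME_UNIT_SECONDS[from_unit]


def halflives_report(k: float, unit: str) -> dict[str, float]:
    """Half-life of rate ``k`` (per ``unit``) expressed in every time base."""
    t = halflife_from_rate(k)
    return {u: convert_time(t, unit, u) for u in TIME_UNIT_SECONDS}


# --------------------------------------------------------------------------
# containers


@dataclass
class KineticTrace:
    """A time course (or melt curve when ``time_unit='C'``)."""

    times: np.ndarray
    signal: np.ndarray
    time_unit: str = "min"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ExchangeSeries:
    """Normalized HDX integrals I(t)/I(first point) vs hours in D2O."""

    times: np.ndarray
    integrals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.times.shape != self.integrals.shape:
            raise ValueError("times and integrals differ in length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if not np.all(np.isfinite(self.integrals)):
            raise ValueError("integrals must be finite")


@dataclass
class ExpFit:
    """Result of a single-exponential folding fit."""

    k: float | None  # per time unit of the trace
    amplitude: float | None  # S0 - Sinf
    offset: float | None  # Sinf
    t_half: float | None
    r2: float | None
    time_unit: str = "min"
    no_transition: bool = False


@dataclass
class ExchangeFit:
    """Fitted HDX parameters (rates in h^-1)."""

    model: str  # "mono" or "biexp"
    i0: float
    i_inf: float = 0.0
    k_ex: float | None = None
    k_ex_fast: float | None = None
    k_ex_slow: float | None = None
    fast_fraction: float | None = None
    r2: float | None = None
    degenerate: bool = False
    boundary: bool = False

    @property
    def t_half(self) -> float | None:
        return None if not self.k_ex else LN2 / self.k_ex

    @property
    def t_half_fast(self) -> float | None:
        return None if not self.k_ex_fast else LN2 / self.k_ex_fast

    @property
    def t_half_slow(self) -> float | None:
        return None if not self.k_ex_slow else LN2 / self.k_ex_slow

    @property
    def fast_ratio_percent(self) -> float | None:
        return None if self.fast_fraction is None else 100.0 * self.fast_fraction


@dataclass
class MeltFit:
    """Boltzmann sigmoid fit of a thermal melt."""

    tm: float  # degrees C
    a1: float  # low-temperature baseline
    a2: float  # high-temperature baseline
    dt: float  # transition width, degrees C
    r2: float


# --------------------------------------------------------------------------
# helpers


def _r2(y: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def _noise_estimate(y: np.ndarray) -> float:
    """Point noise from the median absolute successive difference."""
    if y.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(y)))) / math.sqrt(2.0) * 1.4826


def _loglinear_rate(t: np.ndarray, y: np.ndarray, fallback: float) -> float:
    """Decay rate from a log-linear regression on the positive part of y."""
    mask = y > 0
    if mask.sum() < 2:
        return fallback
    slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
    return -float(slope) if slope < 0 else fallback


# --------------------------------------------------------------------------
# single-exponential folding


def fit_single_exponential(trace: KineticTrace) -> ExpFit:
    """Fit S(t) = offset + amplitude * exp(-k t).

    A trace whose total excursion is within the point-to-point noise is
    reported as ``no_transition`` instead of a rate.
    """
    t, y = trace.times, trace.signal
    if t.size < 5:
        raise FitError("need at least 5 points")
    span = float(np.ptp(y))
    if span <= 5.0 * _noise_estimate(y) or span == 0.0:
        return ExpFit(k=None, amplitude=None, offset=float(np.mean(y)),
                      t_half=None, r2=None, time_unit=trace.time_unit,
                      no_transition=True)

    offset0 = float(y[-1])
    amp0 = float(y[0] - y[-1])
    k0 = _loglinear_rate(t - t[0], (y - offset0) / amp0, fallback=1.0 / np.ptp(t))

    def residual(p):
        a, c, k = p
        return c + a * np.exp(-k * t) - y

    def jac(p):
        a, c, k = p
        e = np.exp(-k * t)
        return np.column_stack([e, np.ones_like(t), -a * t * e])

    res = least_squares(residual, x0=[amp0, offset0, max(k0, 1e-12)],
                        jac=jac, bounds=([-np.inf, -np.inf, 1e-12],
                                         [np.inf, np.inf, np.inf]),
                        **_LSQ_OPTS)
    if not res.success:
        raise FitError("single-exponential fit did not converge")
    a, c, k = res.x
    return ExpFit(k=float(k), amplitude=float(a), offset=float(c),
                  t_half=LN2 / k, r2=_r2(y, residual(res.x) + y),
                  time_unit=trace.time_unit)


# --------------------------------------------------------------------------
# HDX decays


def fit_hdx_mono(series: ExchangeSeries,
                 constrain_floor_to_zero: bool = True) -> ExchangeFit:
    """Fit I(t) = [I(0) - I(inf)] exp(-k_ex t) + I(inf).

    With the default constraint the floor I(inf) is fixed at 0.  A rate
    indistinguishable from 0 over the sampled window sets the ``boundary``
    flag.
    """
    t, y = series.times, series.integrals
    if t.size < 5:
        raise FitError("need at least 5 points")
    i0_0 = float(y[0]) if y[0] > 0 else max(float(np.max(y)), 1e-6)
    k0 = _loglinear_rate(t, y, fallback=1.0 / max(np.ptp(t), 1e-12))

    if constrain_floor_to_zero:
        def residual(p):
            i0, k = p
            return i0 * np.exp(-k * t) - y

        def jac(p):
            i0, k = p
            e = np.exp(-k * t)
            return np.column_stack([e, -i0 * t * e])

        res = least_squares(residual, x0=[i0_0, max(k0, 1e-12)], jac=jac,
                            bounds=([0, 0], [np.inf, np.inf]), **_LSQ_OPTS)
        if not res.success:
            raise FitError("mono-exponential HDX fit did not converge")
        i0, k = res.x
        i_inf = 0.0
    else:
        def residual(p):
            i0, k, i_inf = p
            return (i0 - i_inf) * np.exp(-k * t) + i_inf - y

        def jac(p):
            i0, k, i_inf = p
            e = np.exp(-k * t)
            return np.column_stack([e, -(i0 - i_inf) * t * e, 1.0 - e])

        res = least_squares(residual, x0=[i0_0, max(k0, 1e-12), 0.0], jac=jac,
                            bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
                            **_LSQ_OPTS)
        if not res.success:
            raise FitError("mono-exponential HDX fit did not converge")
        i0, k, i_inf = res.x
    if k < 0:
        raise FitError("negative fitted rate")
    boundary = k * max(np.ptp(t), 1e-12) < 1e-3
    return ExchangeFit(model="mono", i0=float(i0), i_inf=float(i_inf),
                       k_ex=float(k), r2=_r2(y, residual(res.x) + y),
                       boundary=boundary)


def fit_hdx_biexponential(series: ExchangeSeries,
                          degeneracy_ratio: float = 3.0) -> ExchangeFit:
    """Fit I(t) = I0 [f exp(-k_fast t) + (1-f) exp(-k_slow t)], floor 0.

    Rates are ordered after the fit.  If they collapse (k_fast/k_slow below
    ``degeneracy_ratio``) or the fast fraction vanishes, the series is
    effectively monophasic: the mono fit is returned with the ``degenerate``
    flag set.
    """
    t, y = series.times, series.integrals
    if t.size < 8:
        raise FitError("need at least 8 points spanning both phases")
    i0_0 = float(y[0]) if y[0] > 0 else max(float(np.max(y)), 1e-6)

    # seed the slow rate from the late third, the fast rate from the early
    # third after stripping the extrapolated slow component
    late = t >= t[0] + 2.0 * np.ptp(t) / 3.0
    k_slow0 = _loglinear_rate(t[late], y[late], fallback=0.1 / max(np.ptp(t), 1e-12))
    early = t <= t[0] + np.ptp(t) / 3.0
    fast_part = y[early] - 0.5 * i0_0 * np.exp(-k_slow0 * t[early])
    k_fast0 = _loglinear_rate(t[early], fast_part, fallback=10.0 * k_slow0)
    k_fast0 = max(k_fast0, 3.0 * k_slow0)

    def residual(p):
        i0, f, kf, ks = p
        return i0 * (f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t)) - y

    def jac(p):
        i0, f, kf, ks = p
        ef, es = np.exp(-kf * t), np.exp(-ks * t)
        return np.column_stack([
            f * ef + (1 - f) * es,
            i0 * (ef - es),
            -i0 * f * t * ef,
            -i0 * (1 - f) * t * es,
        ])

    res = least_squares(residual, x0=[i0_0, 0.5, max(k_fast0, 1e-10),
                                      max(k_slow0, 1e-12)],
                        jac=jac,
                        bounds=([0, 0, 1e-12, 1e-12], [np.inf, 1, np.inf, np.inf]),
                        **_LSQ_OPTS)
    if not res.success:
        raise FitError("biexponential HDX fit did not converge")
    i0, f, kf, ks = res.x
    if kf < ks:  # enforce fast > slow by relabeling
        kf, ks, f = ks, kf, 1.0 - f
    if ks <= 0 or kf / ks < degeneracy_ratio or f < 0.02 or f > 0.98:
        mono = fit_hdx_mono(series)
        return ExchangeFit(model="mono", i0=mono.i0, i_inf=0.0,
                           k_ex=mono.k_ex, r2=mono.r2, degenerate=True,
                           boundary=mono.boundary)
    return ExchangeFit(model="biexp", i0=float(i0), i_inf=0.0,
                       k_ex_fast=float(kf), k_ex_slow=float(ks),
                       fast_fraction=float(f),
                       r2=_r2(y, residual(res.x) + y))


def split_fit_consistency(
    series: ExchangeSeries,
    regions: list[ExchangeSeries],
    threshold: float = 0.2,
) -> dict:
    """Compare regional mono fits against the global fit.

    ``regions`` are sub-integrations of the same spectra (e.g. the imino
    region split in half) sharing the global time axis.  Reports each
    regional k_ex, the global k_ex, and the maximum relative discrepancy;
    ``consistent`` is False when that exceeds ``threshold``.
    """
    if not regions:
        raise ValueError("no regions supplied")
    global_fit = fit_hdx_mono(series)
    region_ks = [fit_hdx_mono(r).k_ex for r in regions]
    rel = [abs(k - global_fit.k_ex) / global_fit.k_ex for k in region_ks]
    return {
        "k_global": global_fit.k_ex,
        "k_regions": region_ks,
        "max_rel_discrepancy": max(rel),
        "consistent": max(rel) <= threshold,
    }


# --------------------------------------------------------------------------
# thermal melts


def fit_boltzmann_melt(curve: KineticTrace) -> MeltFit:
    """Fit y(T) = A2 + (A1 - A2) / (1 + exp((T - Tm)/dT)).

    ``curve.times`` holds temperatures in degrees C.  Either monotone
    direction is accepted; a curve with no resolvable transition raises
    :class:`FitError`.
    """
    T, y = curve.times, curve.signal
    if T.size < 5:
        raise FitError("need at least 5 points")
    span = float(np.ptp(y))
    if span == 0.0 or span <= 5.0 * _noise_estimate(y):
        raise FitError("no sigmoidal transition detected")

    a1_0, a2_0 = float(np.mean(y[:3])), float(np.mean(y[-3:]))
    half = 0.5 * (a1_0 + a2_0)
    tm0 = float(T[np.argmin(np.abs(y - half))])
    dt0 = max(float(np.ptp(T)) / 10.0, 1e-3)

    def residual(p):
        a1, a2, tm, dt = p
        return a2 + (a1 - a2) / (1.0 + np.exp((T - tm) / dt)) - y

    def jac(p):
        a1, a2, tm, dt = p
        u = (T - tm) / dt
        e = np.exp(u)
        denom = (1.0 + e) ** 2
        return np.column_stack([
            1.0 / (1.0 + e),
            1.0 - 1.0 / (1.0 + e),
            (a1 - a2) * e / (dt * denom),
            (a1 - a2) * e * u / (dt * denom),
        ])

    res = least_squares(residual, x0=[a1_0, a2_0, tm0, dt0], jac=jac,
                        bounds=([-np.inf, -np.inf, T[0] - 50.0, 1e-6],
                                [np.inf, np.inf, T[-1] + 50.0, np.inf]),
                        **_LSQ_OPTS)
    if not res.success:
        raise FitError("Boltzmann melt fit did not converge")
    a1, a2, tm, dt = res.x
    if not (T[0] - 10.0 <= tm <= T[-1] + 10.0):
        raise FitError("fitted Tm far outside the measured range")
    return MeltFit(tm=float(tm), a1=float(a1), a2=float(a2), dt=float(dt),
                   r2=_r2(y, residual(res.x) + y))
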