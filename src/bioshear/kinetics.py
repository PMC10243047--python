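"""Batch suspension-culture growth and metabolite kinetics.

The growth model is simple exponential (balanced) growth,

    C_x(t) = C_x0 * exp(mu * t),

fitted by ordinary least squares on the log scale.  Metabolites follow the
batch mass balance

    q_met * C_x = dC_met / dt,

with a constant specific rate ``q_met`` per cell, which integrates in
closed form against the exponential density.  Partial medium exchanges
(e.g. 50 % replacement on days 1, 3 and 5) reset the concentration
baseline at the event time to ``(1 - f) C(tau-) + f C_fresh`` without
interrupting the cumulative consumption/production bookkeeping.

Units: time in hours, density in cells/ml, concentrations in g/l.  The
ml-to-l factor (``ML_PER_L = 1000``) is applied exactly once, inside
:func:`_density_time_integral` / :func:`predict_metabolite_profile`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hydrodynamics import InvalidInputError

__all__ = [
    "UndefinedStatisticError",
    "ExchangeEvent",
    "CultureTimeSeries",
    "GrowthFit",
    "MetabolicRates",
    "ML_PER_L",
    "fit_growth",
    "predict_density",
    "fold_expansion",
    "apply_exchange_correction",
    "specific_metabolite_rate",
    "predict_metabolite_profile",
    "r_squared",
    "lactate_glucose_ratio",
]

#: millilitres per litre — densities are per ml, concentrations per l.
ML_PER_L = 1000.0


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


@dataclass(frozen=True)
class ExchangeEvent:
    """Partial medium replacement at ``time`` (h).

    ``fraction`` of the working volume is replaced by fresh medium whose
    metabolite concentrations are given by ``fresh`` (g/l; metabolites not
    listed are assumed unchanged, i.e. fresh concentration equal to the
    current one).
    """

    time: float
    fraction: float
    fresh: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidInputError(f"exchange fraction must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class CultureTimeSeries:
    """Sampled viable density and metabolite concentrations over a culture run.

    ``times`` must be strictly increasing with ``times[0] == 0``;
    measurements taken at an exchange time are read as pre-exchange values.
    """

    times: np.ndarray  # h
    viable_density: np.ndarray  # cells/ml
    metabolites: Mapping[str, np.ndarray] = field(default_factory=dict)  # g/l
    exchange_events: tuple[ExchangeEvent, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        cx = np.asarray(self.viable_density, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "viable_density", cx)
        if t.ndim != 1 or t.size < 1:
            raise InvalidInputError("times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if t[0] != 0:
            raise InvalidInputError("time series must start at t = 0")
        if cx.shape != t.shape:
            raise InvalidInputError("viable_density length must match times")
        if np.any(~np.isfinite(cx)) or np.any(cx <= 0):
            raise InvalidInputError("viable densities must be finite and > 0")
        mets = {k: np.asarray(v, dtype=float) for k, v in self.metabolites.items()}
        for name, series in mets.items():
            if series.shape != t.shape:
                raise InvalidInputError(f"metabolite {name!r} length must match times")
        object.__setattr__(self, "metabolites", mets)
        events = tuple(sorted(self.exchange_events, key=lambda e: e.time))
        for ev in events:
            if not t[0] <= ev.time <= t[-1]:
                raise InvalidInputError(
                    f"exchange at t={ev.time} h outside sampled range [{t[0]}, {t[-1]}]"
                )
        object.__setattr__(self, "exchange_events", events)

    # -- convenience I/O -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, "viable_density_cells_per_ml": self.viable_density}
        for name, series in self.metabolites.items():
            data[f"{name}_g_per_l"] = series
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        exchange_events: Sequence[ExchangeEvent] = (),
    ) -> "CultureTimeSeries":
        mets = {}
        for col in frame.columns:
            if col.endswith("_g_per_l"):
                mets[col[: -len("_g_per_l")]] = frame[col].to_numpy(dtype=float)
        return cls(
            times=frame["time_h"].to_numpy(dtype=float),
            viable_density=frame["viable_density_cells_per_ml"].to_numpy(dtype=float),
            metabolites=mets,
            exchange_events=tuple(exchange_events),
        )


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear exponential growth fit: ``C_x = C_x0 exp(mu t)``."""

    mu: float  # 1/h
    initial_density: float  # cells/ml
    r_squared: float  # on the log scale

    def __post_init__(self) -> None:
        if self.initial_density <= 0:
            raise InvalidInputError("initial density must be > 0")


@dataclass(frozen=True)
class MetabolicRates:
    """Specific metabolite rate for one metabolite.

    ``rate`` is a positive magnitude; ``direction`` is ``"consumption"``
    (concentration decreases) or ``"production"``.  ``interval_rates`` are
    signed (negative = consumption) per sampling interval.
    """

    metabolite: str
    rate: float  # g / (cell h), magnitude
    direction: str  # "consumption" | "production"
    interval_times: np.ndarray  # midpoints of sampling intervals (h)
    interval_rates: np.ndarray  # signed, g / (cell h)
    r_squared: float

    @property
    def signed_rate(self) -> float:
        return -self.rate if self.direction == "consumption" else self.rate


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def fit_growth(series: CultureTimeSeries) -> GrowthFit:
    """Fit ``ln C_x = ln C_x0 + mu t`` by ordinary least squares.

    R-squared is reported on the log scale, consistent with the fitting
    objective.  Requires at least two time points with positive densities
    (guaranteed by :class:`CultureTimeSeries`).
    """
    if series.times.size < 2:
        raise InvalidInputError("growth fit requires at least 2 time points")
    t = series.times
    y = np.log(series.viable_density)
    slope, intercept = np.polyfit(t, y, 1)
    pred = intercept + slope * t
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return GrowthFit(mu=float(slope), initial_density=float(np.exp(intercept)), r_squared=r2)


def predict_density(fit: GrowthFit, t) -> np.ndarray | float:
    """Exponential growth prediction ``C_x0 exp(mu t)`` (cells/ml)."""
    return fit.initial_density * np.exp(fit.mu * np.asarray(t, dtype=float))


def fold_expansion(initial: float, final: float) -> float:
    """Final over initial viable density."""
    if not math.isfinite(initial) or initial <= 0:
        raise InvalidInputError(f"initial density must be > 0, got {initial!r}")
    return final / initial


# ---------------------------------------------------------------------------
# Metabolites and exchange accounting
# ---------------------------------------------------------------------------

def _interp_concentration(series: CultureTimeSeries, metabolite: str, t: float) -> float:
    # linear interpolation of observed samples; samples at an exchange time
    # are pre-exchange, so interpolation at tau gives C(tau-)
    return float(np.interp(t, series.times, series.metabolites[metabolite]))


def _cumulative_net_change(series: CultureTimeSeries, metabolite: str) -> np.ndarray:
    """Cumulative exchange-corrected net concentration change at each sample.

    Between consecutive break points (samples and exchange events, merged)
    the observed concentration change counts toward consumption/production;
    at each exchange the baseline jump ``(1-f) C(tau-) + f C_f - C(tau-)``
    is excluded, so the cumulative amount is continuous across events.
    """
    if metabolite not in series.metabolites:
        raise InvalidInputError(f"metabolite {metabolite!r} not present in series")
    t = series.times
    conc = series.metabolites[metabolite]
    events = {ev.time: ev for ev in series.exchange_events}
    knots = np.unique(np.concatenate([t, np.array(sorted(events), dtype=float)])) if events else t

    cum = 0.0
    cum_at_sample = np.zeros_like(t)
    sample_idx = {float(ti): i for i, ti in enumerate(t)}
    prev_conc = conc[0]
    for k, tk in enumerate(knots):
        ck_pre = _interp_concentration(series, metabolite, float(tk))
        if k > 0:
            cum += ck_pre - prev_conc
        i = sample_idx.get(float(tk))
        if i is not None:
            cum_at_sample[i] = cum
        ev = events.get(float(tk))
        if ev is not None:
            fresh = ev.fresh.get(metabolite, ck_pre)
            prev_conc = (1.0 - ev.fraction) * ck_pre + ev.fraction * fresh
        else:
            prev_conc = ck_pre
    return cum_at_sample


def apply_exchange_correction(series: CultureTimeSeries) -> CultureTimeSeries:
    """Convert metabolite concentrations to cumulative net change amounts.

    Returns a series whose metabolite columns hold the cumulative
    exchange-corrected net change (g/l, negative = net consumption) at
    each sampling time.  With no exchange events this is simply
    ``C(t) - C(0)``.  Exchange events are dropped from the returned
    series since their effect is already folded in.
    """
    corrected = {
        name: _cumulative_net_change(series, name) for name in series.metabolites
    }
    return replace(series, metabolites=corrected, exchange_events=())


def _density_time_integral(fit: GrowthFit, t0: float, t1: float) -> float:
    """Integral of predicted density over [t0, t1] in cell h / l."""
    mu, cx0 = fit.mu, fit.initial_density
    if abs(mu) < 1e-12:
        per_ml = cx0 * (t1 - t0)
    else:
        per_ml = cx0 * (math.exp(mu * t1) - math.exp(mu * t0)) / mu
    return per_ml * ML_PER_L


def specific_metabolite_rate(
    series: CultureTimeSeries,
    metabolite: str,
    growth: Optional[GrowthFit] = None,
) -> MetabolicRates:
    """Estimate the specific metabolite rate ``q_met`` from sampled data.

    Per sampling interval, ``q_i = dC_corrected / (dt * mean(C_x at the
    endpoints) / ML_PER_L^-1)`` — i.e. the interval-average density is the
    arithmetic mean of the endpoint densities.  The overall rate divides
    the exchange-corrected total change by the time integral of the fitted
    exponential density, which is the closed-form counterpart of the same
    balance.
    """
    if metabolite not in series.metabolites:
        raise InvalidInputError(f"metabolite {metabolite!r} not present in series")
    if series.times.size < 2:
        raise InvalidInputError("rate estimation requires at least 2 time points")
    if growth is None:
        growth = fit_growth(series)

    cum = _cumulative_net_change(series, metabolite)
    t = series.times
    cx = series.viable_density
    dt = np.diff(t)
    dC = np.diff(cum)
    cx_mean = 0.5 * (cx[:-1] + cx[1:]) * ML_PER_L  # cells/l
    interval_rates = dC / (dt * cx_mean)
    interval_times = 0.5 * (t[:-1] + t[1:])

    total = float(cum[-1])
    integral = _density_time_integral(growth, float(t[0]), float(t[-1]))
    q_signed = total / integral
    direction = "consumption" if q_signed < 0 else "production"

    c0 = float(series.metabolites[metabolite][0])
    predicted = predict_metabolite_profile(
        growth, abs(q_signed), c0, t,
        direction=direction,
        exchange_events=series.exchange_events,
        metabolite=metabolite,
        clamp=False,
    )
    observed = series.metabolites[metabolite]
    try:
        r2 = r_squared(observed, predicted)
    except UndefinedStatisticError:
        r2 = float("nan")
    return MetabolicRates(
        metabolite=metabolite,
        rate=abs(q_signed),
        direction=direction,
        interval_times=interval_times,
        interval_rates=interval_rates,
        r_squared=r2,
    )


def predict_metabolite_profile(
    fit: GrowthFit,
    q: float,
    c0: float,
    times,
    *,
    direction: str = "consumption",
    exchange_events: Sequence[ExchangeEvent] = (),
    metabolite: str = "glucose",
    clamp: bool = True,
) -> np.ndarray:
    """Closed-form metabolite profile under exponential growth.

    Between exchanges,

        C(t) = C_base + s * q * C_x0 * ML_PER_L * (exp(mu t) - exp(mu t_base)) / mu

    with ``s = -1`` for consumption, ``+1`` for production, and the
    ``mu -> 0`` limit handled linearly.  At each exchange event the
    baseline resets to ``(1 - f) C(tau-) + f C_fresh``.  Concentrations
    are floored at zero (with a warning) unless ``clamp=False``.
    """
    if c0 < 0:
        raise InvalidInputError("initial concentration must be >= 0")
    if direction not in ("consumption", "production"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "consumption" else 1.0
    times = np.atleast_1d(np.asarray(times, dtype=float))
    events = sorted((e for e in exchange_events), key=lambda e: e.time)

    def seg_delta(t0: float, t1: float) -> float:
        return sign * q * _density_time_integral(fit, t0, t1)

    out = np.empty_like(times)
    # walk break points (segment starts) event by event
    base_t, base_c = float(times[0]) if times[0] < 0 else 0.0, float(c0)
    ev_idx = 0
    order = np.argsort(times)
    for j in order:
        t = float(times[j])
        # samples taken at an exchange time are pre-exchange values
        while ev_idx < len(events) and events[ev_idx].time < t:
            ev = events[ev_idx]
            c_pre = base_c + seg_delta(base_t, ev.time)
            fresh = ev.fresh.get(metabolite, c_pre)
            base_c = (1.0 - ev.fraction) * c_pre + ev.fraction * fresh
            base_t = ev.time
            ev_idx += 1
        out[j] = base_c + seg_delta(base_t, t)
    if clamp and np.any(out < 0):
        warnings.warn(
            "predicted metabolite depletion: concentrations floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.maximum(out, 0.0)
    return out if out.size > 1 else out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InvalidInputError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("observed series has zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def lactate_glucose_ratio(
    series: CultureTimeSeries,
    window: Optional[tuple[float, float]] = None,
) -> float:
    """Lactate produced over glucose consumed, exchange-corrected.

    Both amounts are cumulative net changes over ``window`` (default: the
    full sampled range); the ratio is the classic overflow-metabolism
    index ``Y_lac/glc``.
    """
    for name in ("glucose", "lactate"):
        if name not in series.metabolites:
            raise InvalidInputError(f"metabolite {name!r} not present in series")
    t = series.times
    if window is None:
        window = (float(t[0]), float(t[-1]))
    ta, tb = window
    if not (t[0] <= ta < tb <= t[-1]):
        raise InvalidInputError(f"window {window} outside sampled range")

    def net(metabolite: str) -> float:
        cum = _cumulative_net_change(series, metabolite)
        return float(np.interp(tb, t, cum) - np.interp(ta, t, cum))

    consumed = -net("glucose")
    produced = net("lactate")
    if consumed <= 0:
        raise UndefinedStatisticError("no net glucose consumption in window")
    return produced / consumed
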