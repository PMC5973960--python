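"""Peak and time-course metrics of conductance curves, and temperature ratios.

Conventions: rise time is 20% -> 80% of peak on the rising branch; the decay
constant is a single-exponential least-squares fit on the log-linearized tail
from the peak down to 10% of the peak.  All reported times are milliseconds;
inputs are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .closed_form import temperature_conductance
from .kinetics import ModelConfig

__all__ = ["CurveMetrics", "TemperatureComparison", "curve_metrics", "compare_temperatures"]

Curve = Union[Callable[[np.ndarray], np.ndarray], Tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class CurveMetrics:
    peak_amplitude: float
    time_to_peak_ms: float
    rise_time_20_80_ms: float
    decay_tau_ms: float

    def to_dict(self) -> dict:
        return {
            "peak_amplitude": self.peak_amplitude,
            "time_to_peak_ms": self.time_to_peak_ms,
            "rise_time_20_80_ms": self.rise_time_20_80_ms,
            "decay_tau_ms": self.decay_tau_ms,
        }


@dataclass(frozen=True)
class TemperatureComparison:
    """Hot/cold ratios of peak amplitude and time to peak, with both metric sets."""

    amp_ratio: float
    time_ratio: float
    cold: CurveMetrics
    hot: CurveMetrics
    T_cold: float
    T_hot: float

    def to_dict(self) -> dict:
        return {
            "T_cold": self.T_cold,
            "T_hot": self.T_hot,
            "amp_ratio": self.amp_ratio,
            "time_ratio": self.time_ratio,
            "cold": self.cold.to_dict(),
            "hot": self.hot.to_dict(),
        }


def _crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First upward crossing time of ``level``, linearly interpolated."""
    above = y >= level
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    y0, y1 = y[k - 1], y[k]
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def curve_metrics(
    curve: Curve,
    window: Tuple[float, float] = (0.0, 5e-3),
    dt: float = 1e-6,
) -> CurveMetrics:
    """Metrics of a nonnegative, single-peaked conductance curve.

    ``curve`` is either a callable of time (seconds) or a ``(t, y)`` sample
    pair.  The peak is located on a dense grid (default 1 us) and, for
    callables, refined by bounded scalar minimization to ~1e-8 s.
    """
    t0, t1 = window
    if callable(curve):
        t = np.arange(t0, t1 + 0.5 * dt, dt)
        y = np.asarray(curve(t), dtype=float)
    else:
        t = np.asarray(curve[0], dtype=float)
        y = np.asarray(curve[1], dtype=float)
        keep = (t >= t0) & (t <= t1)
        t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("curve window contains fewer than 3 samples")
    if np.all(y <= 0):
        raise ValueError("curve is identically zero on the window; metrics undefined")

    k = int(np.argmax(y))
    t_peak, peak = float(t[k]), float(y[k])
    if callable(curve) and 0 < k < len(t) - 1:
        res = minimize_scalar(
            lambda tt: -float(curve(tt)),
            bounds=(t[k - 1], t[k + 1]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success and -res.fun >= peak:
            t_peak, peak = float(res.x), float(-res.fun)

    rising_t, rising_y = t[: k + 1], y[: k + 1]
    rise = _crossing(rising_t, rising_y, 0.8 * peak) - _crossing(rising_t, rising_y, 0.2 * peak)

    # single-exponential tail fit, peak -> 10% of peak (or window end)
    tail = (t >= t_peak) & (y > 0)
    tt, ty = t[tail], y[tail]
    below = np.nonzero(ty <= 0.1 * peak)[0]
    if below.size:
        stop = below[0] + 1
        tt, ty = tt[:stop], ty[:stop]
    if len(tt) >= 2:
        slope = np.polyfit(tt, np.log(ty), 1)[0]
        decay_tau = -1.0 / slope if slope < 0 else np.inf
    else:
        decay_tau = np.nan

    return CurveMetrics(
        peak_amplitude=peak,
        time_to_peak_ms=t_peak * 1e3,
        rise_time_20_80_ms=rise * 1e3,
        decay_tau_ms=decay_tau * 1e3,
    )


def compare_temperatures(
    config: ModelConfig,
    T_cold: float,
    T_hot: float,
    window: Tuple[float, float] = (0.0, 5e-3),
) -> TemperatureComparison:
    """Hot/cold conductance comparison from the closed-form model.

    Both curves are rebuilt from ``config`` with the Q10 law applied at each
    temperature; the ratios are hot over cold, so warming above the reference
    gives an amplitude ratio > 1 and a time ratio < 1.
    """
    if not T_hot >= T_cold:
        raise ValueError(f"T_hot ({T_hot}) must be >= T_cold ({T_cold})")
    cold = curve_metrics(temperature_conductance(config, T_cold), window)
    hot = curve_metrics(temperature_conductance(config, T_hot), window)
    return TemperatureComparison(
        amp_ratio=hot.peak_amplitude / cold.peak_amplitude,
        time_ratio=hot.time_to_peak_ms / cold.time_to_peak_ms,
        cold=cold,
        hot=hot,
        T_cold=T_cold,
        T_hot=T_hot,
    )
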