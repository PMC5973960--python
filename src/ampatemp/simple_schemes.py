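"""Minimal two/three-state AMPA schemes and their temperature-factor fits.

Three reduced kinetic models in the Destexhe tradition, driven by the same
exponential glutamate transient as the full model:

- ``scheme5``: two states, ``C -> O`` at ``r1 * [Glu](t)``, ``O -> C`` at
  ``r2``.
- ``scheme6``: two states with two parallel exits ``O -> C`` at ``r2`` and
  ``r3``.  Only ``r2 + r3`` is observable, so the two rates are
  indistinguishable and the scheme reduces to ``scheme5``.
- ``scheme7``: three states with desensitization: ``C -> O`` at
  ``r1 * [Glu](t)``, ``O -> C`` at ``r2``, ``O -> D`` at ``r3``,
  ``D -> C`` at ``r4``.

The point of the comparison: such schemes have no intrinsic temperature law,
so each rate gets its own fitted Q10 factor.  Fitting them to reference
curves generated by the full analytical model at two temperatures shows
whether a reduced scheme can absorb the temperature dependence — and flags
fitted factors below 1, which would mean conformational changes slowing down
with warming and have no physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .kinetics import GlutamatePulse

__all__ = ["SimpleScheme", "SimpleFitResult", "solve_simple", "fit_simple_to_reference"]

_VARIANT_RATES = {
    "scheme5": ("r1", "r2"),
    "scheme6": ("r1", "r2", "r3"),
    "scheme7": ("r1", "r2", "r3", "r4"),
}

_DEFAULT_RATES = {
    "scheme5": {"r1": 1e7, "r2": 5e3},
    "scheme6": {"r1": 1e7, "r2": 2.5e3, "r3": 2.5e3},
    "scheme7": {"r1": 1e7, "r2": 5e3, "r3": 3e3, "r4": 50.0},
}


@dataclass(frozen=True)
class SimpleScheme:
    """One reduced scheme: variant name, rates and per-rate Q10 factors.

    ``r1`` is a binding rate in 1/(molar s); the others are 1/s.  ``q10``
    holds one multiplicative temperature factor per rate (defaults 1, i.e.
    no temperature dependence until fitted).
    """

    variant: str
    rates: Dict[str, float] = field(default_factory=dict)
    q10: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_RATES:
            raise ValueError(f"unknown variant {self.variant!r}; use scheme5/scheme6/scheme7")
        names = _VARIANT_RATES[self.variant]
        rates = dict(_DEFAULT_RATES[self.variant])
        rates.update(self.rates)
        extra = set(rates) - set(names)
        if extra:
            raise ValueError(f"{self.variant} does not use rates {sorted(extra)}")
        for k, v in rates.items():
            if not v > 0:
                raise ValueError(f"rate {k} must be positive, got {v!r}")
        q10 = {k: 1.0 for k in names}
        q10.update(self.q10)
        for k, v in q10.items():
            if not v > 0:
                raise ValueError(f"Q10 factor for {k} must be positive, got {v!r}")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "q10", q10)

    @property
    def rate_names(self) -> Tuple[str, ...]:
        return _VARIANT_RATES[self.variant]

    def at_temperature_step(self, n_steps: float = 1.0) -> "SimpleScheme":
        """Rates after ``n_steps`` ten-degree steps of each rate's own Q10."""
        return SimpleScheme(
            variant=self.variant,
            rates={k: v * self.q10[k] ** n_steps for k, v in self.rates.items()},
            q10=dict(self.q10),
        )

    def reduced(self) -> "SimpleScheme":
        """scheme6 collapsed onto scheme5 by merging the indistinguishable exits."""
        if self.variant != "scheme6":
            return self
        return SimpleScheme(
            variant="scheme5",
            rates={"r1": self.rates["r1"], "r2": self.rates["r2"] + self.rates["r3"]},
            q10={"r1": self.q10["r1"], "r2": self.q10["r2"]},
        )


def solve_simple(
    scheme: SimpleScheme,
    pulse: GlutamatePulse,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> np.ndarray:
    """Open fraction of the scheme on ``t_grid`` (seconds), starting all closed.

    Integrates the scheme's master equation with the binding transition
    driven by ``r1 * A * exp(-omega t)``; the closed system conserves total
    fraction 1.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    r = scheme.rates
    variant = scheme.variant if scheme.variant != "scheme6" else "scheme5"
    if scheme.variant == "scheme6":
        r = scheme.reduced().rates

    A, omega = pulse.A, pulse.omega

    if variant == "scheme5":
        def rhs(t, s):
            bind = r["r1"] * A * np.exp(-omega * t) * s[0]
            close = r["r2"] * s[1]
            return np.array([close - bind, bind - close])
        s0 = np.array([1.0, 0.0])
        open_idx = 1
    else:  # scheme7
        def rhs(t, s):
            bind = r["r1"] * A * np.exp(-omega * t) * s[0]
            close = r["r2"] * s[1]
            desens = r["r3"] * s[1]
            resens = r["r4"] * s[2]
            return np.array([close + resens - bind, bind - close - desens, desens - resens])
        s0 = np.array([1.0, 0.0, 0.0])
        open_idx = 1

    sol = solve_ivp(
        rhs, (float(t_grid[0]), float(t_grid[-1])), s0, method="LSODA",
        t_eval=t_grid, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"simple-scheme integration failed: {sol.message}; "
            f"variant={scheme.variant}, rates={r}"
        )
    return sol.y[open_idx]


@dataclass(frozen=True)
class SimpleFitResult:
    """Outcome of fitting a reduced scheme to two-temperature reference curves."""

    scheme: SimpleScheme            # fitted cold-temperature rates + per-rate Q10
    amplitude: float                # conductance per unit open fraction
    residual_norm: float
    cold_residual_norm: float
    hot_residual_norm: float
    hot_peak_rel_error: float       # (model - reference)/reference at the hot peak
    unphysical_q10: Tuple[str, ...] # fitted factors < 1 (no physical meaning)
    converged: bool

    def to_dict(self) -> dict:
        return {
            "variant": self.scheme.variant,
            "rates": dict(self.scheme.rates),
            "q10": dict(self.scheme.q10),
            "amplitude": self.amplitude,
            "residual_norm": self.residual_norm,
            "cold_residual_norm": self.cold_residual_norm,
            "hot_residual_norm": self.hot_residual_norm,
            "hot_peak_rel_error": self.hot_peak_rel_error,
            "unphysical_q10": list(self.unphysical_q10),
            "converged": self.converged,
        }


def fit_simple_to_reference(
    scheme: SimpleScheme,
    t_grid: np.ndarray,
    g_cold: np.ndarray,
    g_hot: np.ndarray,
    pulse: Optional[GlutamatePulse] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> SimpleFitResult:
    """Fit rates and per-rate Q10 factors to cold/hot reference curves.

    The cold curve constrains the base rates and the shared amplitude; the
    hot curve constrains the per-rate temperature factors (one ten-degree
    step).  Bounded log-space trust-region least squares with ``n_starts``
    seeded multi-starts; the best-so-far result is returned even without
    formal convergence.
    """
    if pulse is None:
        pulse = GlutamatePulse()
    t_grid = np.asarray(t_grid, dtype=float)
    g_cold = np.asarray(g_cold, dtype=float)
    g_hot = np.asarray(g_hot, dtype=float)
    names = scheme.rate_names
    scale = float(max(g_cold.max(), g_hot.max()))
    if scale <= 0:
        raise ValueError("reference curves are non-positive; nothing to fit")

    # parameters: log10(amplitude), log10(rates...), log10(q10 factors...)
    base = np.array([scheme.rates[k] for k in names])
    lo = np.concatenate(([np.log10(scale * 1e-2)], np.log10(base) - 2, np.full(len(names), np.log10(0.2))))
    hi = np.concatenate(([np.log10(scale * 1e2)], np.log10(base) + 2, np.full(len(names), np.log10(10.0))))

    def unpack(theta):
        amp = 10.0 ** theta[0]
        rates = {k: 10.0 ** v for k, v in zip(names, theta[1 : 1 + len(names)])}
        q10 = {k: 10.0 ** v for k, v in zip(names, theta[1 + len(names) :])}
        return amp, SimpleScheme(variant=scheme.variant, rates=rates, q10=q10)

    def residuals(theta):
        amp, sch = unpack(theta)
        cold = amp * solve_simple(sch, pulse, t_grid, rtol=1e-8, atol=1e-12)
        hot = amp * solve_simple(sch.at_temperature_step(), pulse, t_grid, rtol=1e-8, atol=1e-12)
        return np.concatenate([cold - g_cold, hot - g_hot]) / scale

    rng = np.random.default_rng(seed)
    x0_center = np.concatenate(([np.log10(scale)], np.log10(base), np.full(len(names), np.log10(2.0))))
    x0_center = np.clip(x0_center, lo, hi)
    best = None
    any_converged = False
    for start in range(n_starts):
        x0 = x0_center if start == 0 else np.clip(
            x0_center + rng.uniform(-0.7, 0.7, size=x0_center.shape), lo, hi
        )
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10)
        except Exception:
            continue
        any_converged = any_converged or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all multi-start fits failed")

    amp, fitted = unpack(best.x)
    n = len(t_grid)
    r = best.fun * scale
    cold_res = float(np.linalg.norm(r[:n]))
    hot_res = float(np.linalg.norm(r[n:]))
    hot_model = amp * solve_simple(fitted.at_temperature_step(), pulse, t_grid)
    k = int(np.argmax(g_hot))
    hot_peak_err = float((hot_model[k] - g_hot[k]) / g_hot[k])
    unphysical = tuple(k_ for k_ in names if fitted.q10[k_] < 1.0)
    return SimpleFitResult(
        scheme=fitted,
        amplitude=amp,
        residual_norm=float(np.linalg.norm(r)),
        cold_residual_norm=cold_res,
        hot_residual_norm=hot_res,
        hot_peak_rel_error=hot_peak_err,
        unphysical_q10=unphysical,
        converged=any_converged,
    )
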