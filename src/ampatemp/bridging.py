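"""Temperature bridging: fit, Q10-rescale, regenerate, refit.

The pipeline translates a synaptic conductance waveform measured (or
modeled) at one temperature into the corresponding waveform at another,
using the mechanistic model as the carrier of the temperature law:

1. fit the closed-form model (rates, glutamate constants, amplitude) to the
   source curve under physiological bounds;
2. multiply all fitted rate constants by ``Q10 ** (dT / 10)``;
3. regenerate the conductance curve at the target temperature;
4. refit whatever phenomenological family the downstream simulator wants
   (alpha, single- or dual-exponential).

Because the temperature step is a common multiplication of all rates, the
output is insensitive to degeneracy among the fitted parameters: any
parameter set reproducing the source curve maps to (nearly) the same target
curve.  The binding rate and the glutamate amplitude enter the dynamics only
as the product ``k_b * A``, so they are fitted as one parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .closed_form import conductance, solve_scheme2
from .kinetics import (
    GlutamatePulse,
    ModelConfig,
    RateConstants,
    TemperatureModel,
)

__all__ = [
    "AnalyticalFit",
    "PhenomenologicalFit",
    "BridgeResult",
    "generate_fixture",
    "fit_analytical",
    "fit_phenomenological",
    "bridge",
]

# reference values around which the default (one-decade) fit bounds are set
_REF = {"kbA": 1e7 * 7.48e-4, "k_u": 8e3, "k_o": 20e3, "k_c": 10e3, "k_d": 4e3, "k_r": 15.0, "omega": 2471.0}
_PARAM_ORDER = ("kbA", "k_u", "k_o", "k_c", "k_d", "k_r", "omega")
_A_CONVENTION = 7.48e-4  # molar; fixed so that k_b = kbA / A stays in familiar units


def generate_fixture(
    config: ModelConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_end: float = 5e-3,
    dt: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic conductance series from the closed form, optionally noisy.

    Samples ``g(t)`` on a regular grid (default 0-5 ms at 1 us) and applies
    multiplicative Gaussian noise of relative standard deviation
    ``noise_sd``, seeded and bit-reproducible.  Returns ``(t, g)`` in seconds
    and conductance units.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    g = conductance(solve_scheme2(config), config)(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise_sd * rng.standard_normal(g.shape))
    return t, g


@dataclass(frozen=True)
class AnalyticalFit:
    """Fit report for the closed-form model against a conductance series."""

    config: ModelConfig
    amplitude: float          # nu * g4, the overall conductance scale
    residual_norm: float
    rel_rms: float            # ||model - data|| / ||data||
    converged: bool
    n_starts: int

    def to_dict(self) -> dict:
        return {
            "params": self.config.to_dict(),
            "amplitude": self.amplitude,
            "residual_norm": self.residual_norm,
            "rel_rms": self.rel_rms,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def _model_curve(theta: np.ndarray, t: np.ndarray, n_orders: int) -> np.ndarray:
    amp = 10.0 ** theta[0]
    vals = {k: 10.0 ** v for k, v in zip(_PARAM_ORDER, theta[1:])}
    cfg = ModelConfig(
        rates=RateConstants(
            k_b=vals["kbA"] / _A_CONVENTION, k_u=vals["k_u"], k_o=vals["k_o"],
            k_c=vals["k_c"], k_d=vals["k_d"], k_r=vals["k_r"],
        ),
        pulse=GlutamatePulse(A=_A_CONVENTION, omega=vals["omega"]),
        n_orders=n_orders,
        nu=1.0,
    )
    g = conductance(solve_scheme2(cfg), replace(cfg, weights=replace(cfg.weights, g4=amp)))
    return g(t)


def fit_analytical(
    t: np.ndarray,
    g: np.ndarray,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_orders: int = 4,
    n_starts: int = 8,
    seed: int = 0,
) -> AnalyticalFit:
    """Fit the closed-form model to a conductance time series.

    Free parameters are the product ``k_b * A`` (the two are not separately
    identifiable), the five remaining rates, the glutamate decay ``omega``
    and an overall amplitude absorbing ``nu * g4``.  Bounds default to one
    decade around the reference parameter set.  Fitting is bounded
    trust-region least squares in log space with seeded multi-starts; the
    best result is returned even if the optimizer did not formally converge.

    The contract is recovery in curve space: distinct parameter sets may fit
    equally well, but the regenerated curve must match the data.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(t) < 50:
        raise ValueError("need at least 50 samples to fit the model")
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0 or np.all(g <= 0):
        raise ValueError("curve is identically zero/non-positive; nothing to fit")
    scale = float(np.max(g))

    user = bounds or {}
    lo = [np.log10(scale * 1e-3)]
    hi = [np.log10(scale * 1e3)]
    for name in _PARAM_ORDER:
        b_lo, b_hi = user.get(name, (0.1 * _REF[name], 10.0 * _REF[name]))
        lo.append(np.log10(b_lo))
        hi.append(np.log10(b_hi))
    lo, hi = np.array(lo), np.array(hi)

    def residuals(theta):
        return (_model_curve(theta, t, n_orders) - g) / scale

    x0_center = np.clip(
        np.concatenate(([np.log10(scale * 2)], [np.log10(_REF[k]) for k in _PARAM_ORDER])),
        lo, hi,
    )
    rng = np.random.default_rng(seed)
    best = None
    any_ok = False
    for start in range(n_starts):
        x0 = x0_center if start == 0 else np.clip(
            x0_center + rng.uniform(-0.5, 0.5, size=x0_center.shape), lo, hi
        )
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        any_ok = any_ok or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("analytical fit failed from every start")

    amp = 10.0 ** best.x[0]
    vals = {k: 10.0 ** v for k, v in zip(_PARAM_ORDER, best.x[1:])}
    nu = 0.13
    cfg = ModelConfig(
        rates=RateConstants(
            k_b=vals["kbA"] / _A_CONVENTION, k_u=vals["k_u"], k_o=vals["k_o"],
            k_c=vals["k_c"], k_d=vals["k_d"], k_r=vals["k_r"],
        ),
        pulse=GlutamatePulse(A=_A_CONVENTION, omega=vals["omega"]),
        weights=replace(ModelConfig().weights, g4=amp / nu),
        n_orders=n_orders,
        nu=nu,
    )
    model = conductance(solve_scheme2(cfg), cfg)(t)
    return AnalyticalFit(
        config=cfg,
        amplitude=amp,
        residual_norm=float(np.linalg.norm(model - g)),
        rel_rms=float(np.linalg.norm(model - g) / gnorm),
        converged=any_ok,
        n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# phenomenological waveform families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenomenologicalFit:
    """A fitted waveform family: alpha, single_exp or dual_exp.

    Parameter conventions: alpha ``g_max (t/tau) exp(1 - t/tau)``;
    single_exp ``amp exp(-t/tau)``; dual_exp ``A exp(alpha t) - B exp(beta t)``
    with both exponents negative (decaying).
    """

    family: str
    params: Dict[str, float]
    residual_norm: float
    rel_rms: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "alpha":
            return p["g_max"] * (t / p["tau"]) * np.exp(1.0 - t / p["tau"])
        if self.family == "single_exp":
            return p["amp"] * np.exp(-t / p["tau"])
        return p["A"] * np.exp(p["alpha"] * t) - p["B"] * np.exp(p["beta"] * t)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "residual_norm": self.residual_norm,
            "rel_rms": self.rel_rms,
        }


def fit_phenomenological(t: np.ndarray, g: np.ndarray, family: str = "dual_exp") -> PhenomenologicalFit:
    """Least-squares fit of a phenomenological waveform to a conductance curve."""
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0:
        raise ValueError("curve is identically zero; nothing to fit")
    k = int(np.argmax(g))
    peak, t_peak = float(g[k]), float(max(t[k], t[1] if len(t) > 1 else 1e-6))

    if family == "alpha":
        def model(x):
            g_max, tau = 10.0 ** x
            return g_max * (t / tau) * np.exp(1.0 - t / tau)
        x0 = np.log10([peak, t_peak])
        names = ("g_max", "tau")
    elif family == "single_exp":
        def model(x):
            amp, tau = 10.0 ** x
            return amp * np.exp(-t / tau)
        x0 = np.log10([peak, 2.0 * t_peak])
        names = ("amp", "tau")
    elif family == "dual_exp":
        def model(x):
            A, B, na, nb = 10.0 ** x
            return A * np.exp(-na * t) - B * np.exp(-nb * t)
        # slow decay ~ 1/(2 t_peak), fast rise ~ 5/t_peak
        amp0 = 2.0 * peak
        x0 = np.log10([amp0, amp0, 0.5 / t_peak, 5.0 / t_peak])
        names = ("A", "B", "alpha", "beta")
    else:
        raise ValueError(f"unknown family {family!r}; use alpha, single_exp or dual_exp")

    res = least_squares(lambda x: (model(x) - g) / peak, x0, xtol=1e-14, ftol=1e-14)
    vals = 10.0 ** res.x
    if family == "dual_exp":
        params = {"A": vals[0], "B": vals[1], "alpha": -vals[2], "beta": -vals[3]}
    else:
        params = dict(zip(names, vals))
    fit_curve = model(res.x)
    return PhenomenologicalFit(
        family=family,
        params=params,
        residual_norm=float(np.linalg.norm(fit_curve - g)),
        rel_rms=float(np.linalg.norm(fit_curve - g) / gnorm),
    )


@dataclass(frozen=True)
class BridgeResult:
    """Everything produced by one bridging run."""

    fit: AnalyticalFit                    # source-temperature fit
    rescaled_config: ModelConfig          # rates x Q10**(dT/10), exactly
    time: np.ndarray
    source_curve: np.ndarray              # fitted model at T_source
    bridged_curve: np.ndarray             # regenerated model at T_target
    phenomenological: PhenomenologicalFit
    T_source: float
    T_target: float
    q10: float

    def to_dict(self) -> dict:
        return {
            "T_source": self.T_source,
            "T_target": self.T_target,
            "Q10": self.q10,
            "fit": self.fit.to_dict(),
            "rescaled_params": self.rescaled_config.to_dict(),
            "phenomenological": self.phenomenological.to_dict(),
            "time_ms": (self.time * 1e3).tolist(),
            "source_curve": self.source_curve.tolist(),
            "bridged_curve": self.bridged_curve.tolist(),
        }


def bridge(
    t: np.ndarray,
    g: np.ndarray,
    T_source: float,
    T_target: float,
    q10: float = 2.4,
    family: str = "dual_exp",
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> BridgeResult:
    """Translate a conductance curve from ``T_source`` to ``T_target``.

    Chains fit -> common Q10 rescale of all six rates -> closed-form
    regeneration -> phenomenological refit.  With ``T_target == T_source``
    the bridge is the identity and the output curve equals the fitted curve.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    fit = fit_analytical(t, g, bounds=bounds, n_starts=n_starts, seed=seed)
    factor = q10 ** ((T_target - T_source) / 10.0)
    rescaled = replace(
        fit.config,
        rates=fit.config.rates.scaled(factor),
        temperature=TemperatureModel(Q10=q10, T_ref=T_source),
    )
    source_curve = conductance(solve_scheme2(fit.config), fit.config)(t)
    bridged = conductance(solve_scheme2(rescaled), rescaled)(t)
    phen = fit_phenomenological(t, bridged, family=family)
    return BridgeResult(
        fit=fit,
        rescaled_config=rescaled,
        time=t,
        source_curve=source_curve,
        bridged_curve=bridged,
        phenomenological=phen,
        T_source=T_source,
        T_target=T_target,
        q10=q10,
    )
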