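"""Kinetic parameters of the AMPA-receptor scheme and their temperature scaling.

The model describes a tetrameric AMPA receptor whose conformational dynamics
are a Markov chain over closed/bound (``C_i``), open (``O_i``) and
desensitized (``D_i``) states, driven by a glutamate concentration transient
that decays as a single exponential.  Temperature enters through a single
Q10 coefficient multiplying every rate constant.

All rates are in 1/s (binding in 1/(molar*s)), concentrations in molar and
times in seconds.  Millisecond conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "RateConstants",
    "GlutamatePulse",
    "TemperatureModel",
    "ConductanceWeights",
    "ModelConfig",
    "scale_rates",
    "scale_config",
    "binding_rate",
]

RATE_NAMES = ("k_b", "k_u", "k_o", "k_c", "k_d", "k_r")


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """The six transition rates of the receptor kinetic scheme.

    Defaults are the fitted calyx-of-Held values: binding ``k_b`` (1/(M*s)),
    unbinding ``k_u``, channel opening ``k_o``, closing ``k_c``,
    desensitization ``k_d`` and resensitization ``k_r`` (all 1/s).
    """

    k_b: float = 1e7
    k_u: float = 8e3
    k_o: float = 20e3
    k_c: float = 10e3
    k_d: float = 4e3
    k_r: float = 15.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            _require_positive(name, getattr(self, name))

    def scaled(self, factor: float) -> "RateConstants":
        """Return a copy with every rate multiplied by ``factor``."""
        _require_positive("factor", factor)
        return RateConstants(**{name: factor * getattr(self, name) for name in RATE_NAMES})

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in RATE_NAMES}


@dataclass(frozen=True)
class GlutamatePulse:
    """Exponentially decaying glutamate transient at the postsynaptic density.

    Concentration is ``A * exp(-omega * t)`` with peak amplitude ``A`` (molar)
    and decay rate ``omega`` (1/s).
    """

    A: float = 7.48e-4
    omega: float = 2471.0

    def __post_init__(self) -> None:
        _require_positive("A", self.A)
        _require_positive("omega", self.omega)

    def concentration(self, t):
        return self.A * np.exp(-self.omega * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class TemperatureModel:
    """Q10 law for rate constants, ``factor = Q10 ** ((T - T_ref) / 10)``.

    ``Q10_diff`` is an optional, normally disabled, coefficient applied to the
    glutamate decay rate ``omega`` only.  It is a crude stand-in for a faster
    diffusive clearance of transmitter at higher temperature; the model's
    default position is that postsynaptic receptor kinetics dominate the
    temperature response, so ``omega`` is left untouched.
    """

    Q10: float = 2.4
    T_ref: float = 25.0
    Q10_diff: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("Q10", self.Q10)
        if not math.isfinite(self.T_ref):
            raise ValueError(f"T_ref must be finite, got {self.T_ref!r}")
        if self.Q10_diff is not None:
            _require_positive("Q10_diff", self.Q10_diff)

    def factor(self, T: float) -> float:
        if not (isinstance(T, (int, float)) and math.isfinite(T)):
            raise ValueError(f"temperature must be finite, got {T!r}")
        return self.Q10 ** ((T - self.T_ref) / 10.0)

    def diffusion_factor(self, T: float) -> float:
        if self.Q10_diff is None:
            return 1.0
        if not (isinstance(T, (int, float)) and math.isfinite(T)):
            raise ValueError(f"temperature must be finite, got {T!r}")
        return self.Q10_diff ** ((T - self.T_ref) / 10.0)


@dataclass(frozen=True)
class ConductanceWeights:
    """Sub-conductance fractions ``a_1..a_4`` and the full-level conductance ``g4``.

    An open receptor with ``i`` glutamate molecules bound conducts a fraction
    ``a_i`` of the fully (4-fold) bound open-state conductance ``g4``.  By
    convention ``a_4 = 1``; the convention is not enforced so that degenerate
    weight sets (e.g. all zero) remain representable.
    """

    a: tuple = (0.1, 0.4, 0.7, 1.0)
    g4: float = 1.0

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.a)
        if len(a) != 4:
            raise ValueError(f"exactly four subconductance weights required, got {len(a)}")
        for i, v in enumerate(a, start=1):
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"a{i} must lie in [0, 1], got {v!r}")
        object.__setattr__(self, "a", a)
        _require_positive("g4", self.g4)


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of the analytical conductance model.

    ``n_orders`` truncates the sub-conductance cascade (1..4) and ``nu`` is
    the overall normalization of state fractions (default 0.13), calibrated so
    that the analytical bound-channel sum matches the absolute bound fraction
    of the detailed spatial simulation at the conductance peak.
    """

    rates: RateConstants = field(default_factory=RateConstants)
    pulse: GlutamatePulse = field(default_factory=GlutamatePulse)
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    weights: ConductanceWeights = field(default_factory=ConductanceWeights)
    n_orders: int = 4
    nu: float = 0.13

    def __post_init__(self) -> None:
        if not (isinstance(self.n_orders, int) and 1 <= self.n_orders <= 4):
            raise ValueError(f"n_orders must be an integer in 1..4, got {self.n_orders!r}")
        if not (math.isfinite(self.nu) and 0 < self.nu <= 1):
            raise ValueError(f"nu must lie in (0, 1], got {self.nu!r}")

    # -- flat-key serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = self.rates.as_dict()
        d.update(A=self.pulse.A, omega=self.pulse.omega)
        d.update(Q10=self.temperature.Q10, T_ref=self.temperature.T_ref)
        if self.temperature.Q10_diff is not None:
            d["Q10_diff"] = self.temperature.Q10_diff
        for i, v in enumerate(self.weights.a, start=1):
            d[f"a{i}"] = v
        d.update(g4=self.weights.g4, n_orders=self.n_orders, nu=self.nu)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = set(RATE_NAMES) | {
            "A", "omega", "Q10", "T_ref", "Q10_diff",
            "a1", "a2", "a3", "a4", "g4", "n_orders", "nu",
        }
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        missing = sorted(known - {"Q10_diff"} - set(d))
        if missing:
            raise ValueError(f"missing config keys: {', '.join(missing)}")
        return cls(
            rates=RateConstants(**{k: float(d[k]) for k in RATE_NAMES}),
            pulse=GlutamatePulse(A=float(d["A"]), omega=float(d["omega"])),
            temperature=TemperatureModel(
                Q10=float(d["Q10"]),
                T_ref=float(d["T_ref"]),
                Q10_diff=float(d["Q10_diff"]) if "Q10_diff" in d else None,
            ),
            weights=ConductanceWeights(
                a=(float(d["a1"]), float(d["a2"]), float(d["a3"]), float(d["a4"])),
                g4=float(d["g4"]),
            ),
            n_orders=int(d["n_orders"]),
            nu=float(d["nu"]),
        )


def scale_rates(rates: RateConstants, temp: TemperatureModel, T: float) -> RateConstants:
    """All six rate constants multiplied by ``Q10 ** ((T - T_ref) / 10)``.

    With the default Q10 = 2.4 and T_ref = 25 C, the single step used in the
    original study (25 -> 35 C) multiplies every rate by exactly 2.4.
    """
    return rates.scaled(temp.factor(T))


def scale_config(config: ModelConfig, T: float) -> ModelConfig:
    """Config rebuilt at temperature ``T``.

    Rates follow the Q10 law; the glutamate decay rate ``omega`` is scaled by
    ``Q10_diff`` only when that optional coefficient is set.
    """
    rates = scale_rates(config.rates, config.temperature, T)
    pulse = config.pulse
    dfac = config.temperature.diffusion_factor(T)
    if dfac != 1.0:
        pulse = replace(pulse, omega=pulse.omega * dfac)
    return replace(config, rates=rates, pulse=pulse)


def binding_rate(rates: RateConstants, pulse: GlutamatePulse, t):
    """Time-dependent binding rate ``k_b(t) = k_b * A * exp(-omega * t)`` in 1/s."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("binding_rate requires finite t >= 0")
    out = rates.k_b * pulse.A * np.exp(-pulse.omega * t)
    return float(out) if out.ndim == 0 else out
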