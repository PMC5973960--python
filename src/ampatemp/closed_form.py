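"""Closed-form solution of the uncoupled receptor scheme.

The uncoupling step splits the twelve coupled state equations of the
four-mesh scheme into four independent pairs, chained only through the
scaling function ``lambda_i(t) = x_{i-1}(t)`` (with ``lambda_1 = 1``):

    dx_i/dt = k_b A exp(-omega t) lambda_i(t) - (k_o + k_u + k_d) x_i
    dy_i/dt = k_o x_i - k_c y_i
    dz_i/dt = k_d x_i - k_r z_i

Every trajectory of this cascade is a finite sum of terms
``c * t**n * exp(-r t)``, so the whole model lives in a small closed
algebra (:class:`ExpSum`) and first-order linear ODEs with such forcings
are solved exactly by a coefficient recurrence — no symbolic engine and no
numerical integrator on the happy path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, List, Sequence, Tuple

import numpy as np

from .kinetics import ModelConfig, scale_config

__all__ = [
    "ExpSum",
    "FirstOrderConstants",
    "OrderSolution",
    "solve_linear_exp_ode",
    "first_order_open",
    "solve_scheme2",
    "conductance",
    "Conductance",
    "temperature_conductance",
]

#: relative tolerance at which two decay rates are treated as coincident
RESONANCE_RTOL = 1e-9
#: relative tolerance for merging equal (rate, order) terms into canonical form
_MERGE_RTOL = 1e-12


def _canonical(terms: Iterable[Tuple[float, float, int]]) -> Tuple[Tuple[float, float, int], ...]:
    """Merge terms sharing (poly order, rate) and drop exact zeros."""
    by_order: dict = {}
    for c, r, n in terms:
        c = float(c)
        r = float(r)
        n = int(n)
        if n < 0:
            raise ValueError(f"polynomial order must be >= 0, got {n}")
        if not (math.isfinite(c) and math.isfinite(r)):
            raise ValueError(f"non-finite term ({c}, {r}, {n})")
        bucket = by_order.setdefault(n, [])
        for k, (cc, rr) in enumerate(bucket):
            if abs(r - rr) <= _MERGE_RTOL * max(1.0, abs(r), abs(rr)):
                bucket[k] = (cc + c, rr)
                break
        else:
            bucket.append((c, r))
    out = []
    for n in sorted(by_order):
        for c, r in sorted(by_order[n], key=lambda cr: cr[1]):
            if c != 0.0:
                out.append((c, r, n))
    return tuple(out)


@dataclass(frozen=True)
class ExpSum:
    """A function ``sum_j c_j * t**n_j * exp(-r_j t)`` in canonical form.

    Canonical means no two terms share the same (rate, order) pair; the empty
    sum is the zero function.  The class is closed under addition,
    multiplication and the linear-ODE solve below.
    """

    terms: Tuple[Tuple[float, float, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", _canonical(self.terms))

    # -- constructors ---------------------------------------------------------

    @staticmethod
    def zero() -> "ExpSum":
        return ExpSum(())

    @staticmethod
    def constant(c: float) -> "ExpSum":
        return ExpSum(((c, 0.0, 0),))

    @staticmethod
    def exponential(c: float, rate: float) -> "ExpSum":
        """The single term ``c * exp(-rate * t)``."""
        return ExpSum(((c, rate, 0),))

    # -- algebra --------------------------------------------------------------

    def __add__(self, other: "ExpSum") -> "ExpSum":
        return ExpSum(self.terms + other.terms)

    def __sub__(self, other: "ExpSum") -> "ExpSum":
        return self + (-other)

    def __neg__(self) -> "ExpSum":
        return ExpSum(tuple((-c, r, n) for c, r, n in self.terms))

    def __mul__(self, other):
        if isinstance(other, ExpSum):
            prod = [
                (c1 * c2, r1 + r2, n1 + n2)
                for c1, r1, n1 in self.terms
                for c2, r2, n2 in other.terms
            ]
            return ExpSum(tuple(prod))
        return ExpSum(tuple((float(other) * c, r, n) for c, r, n in self.terms))

    __rmul__ = __mul__

    def derivative(self) -> "ExpSum":
        out = []
        for c, r, n in self.terms:
            if n > 0:
                out.append((c * n, r, n - 1))
            out.append((-c * r, r, n))
        return ExpSum(tuple(out))

    # -- evaluation -----------------------------------------------------------

    def __call__(self, t):
        tt = np.asarray(t, dtype=float)
        out = np.zeros_like(tt)
        for c, r, n in self.terms:
            term = c * np.exp(-r * tt)
            if n:
                term = term * tt**n
            out = out + term
        return float(out) if out.ndim == 0 else out

    def is_zero(self) -> bool:
        return not self.terms


@dataclass(frozen=True)
class FirstOrderConstants:
    """The rate combinations appearing in the explicit first-order solution.

    ``S = k_c - omega``, ``P = k_d + k_o + k_u - omega`` and
    ``R = -k_c + k_d + k_o + k_u``; the identity ``R + S = P`` holds by
    construction.
    """

    S: float
    P: float
    R: float

    @classmethod
    def from_config(cls, config: ModelConfig) -> "FirstOrderConstants":
        r, om = config.rates, config.pulse.omega
        return cls(
            S=r.k_c - om,
            P=r.k_d + r.k_o + r.k_u - om,
            R=-r.k_c + r.k_d + r.k_o + r.k_u,
        )


@dataclass(frozen=True)
class OrderSolution:
    """Closed-form state fractions of a single mesh of the cascade.

    ``x``: bound-closed ``C_i``; ``y``: open ``O_i``; ``z``: desensitized
    ``D_i``; ``lambda_source`` is the driving scale (1 for the first order,
    the previous order's ``x`` above it).
    """

    order: int
    x: ExpSum
    y: ExpSum
    z: ExpSum
    lambda_source: ExpSum


def solve_linear_exp_ode(forcing: ExpSum, decay: float, init: float = 0.0) -> ExpSum:
    """Exact solution of ``u' = forcing(t) - decay * u``, ``u(0) = init``.

    For a forcing term ``c t**n exp(-r t)`` with ``r`` away from ``decay``
    the particular solution is a degree-``n`` polynomial times ``exp(-r t)``
    obtained by back-substitution; when ``|r - decay|`` is within
    ``RESONANCE_RTOL`` (relative) the resonant form
    ``c t**(n+1)/(n+1) exp(-decay t)`` is used instead.  The homogeneous mode
    ``exp(-decay t)`` absorbs the initial condition.
    """
    if not (math.isfinite(decay) and decay > 0):
        raise ValueError(f"decay rate must be positive and finite, got {decay!r}")
    out: List[Tuple[float, float, int]] = []
    hom = float(init)  # coefficient of exp(-decay t)
    for c, r, n in forcing.terms:
        a = decay - r
        if abs(a) <= RESONANCE_RTOL * max(abs(decay), abs(r)):
            # resonant: particular solution vanishes at t=0
            out.append((c / (n + 1), decay, n + 1))
            continue
        # u_p = Q(t) exp(-r t) with Q' + a Q = c t**n
        q = [0.0] * (n + 1)
        q[n] = c / a
        for k in range(n, 0, -1):
            q[k - 1] = -k * q[k] / a
        for k, qk in enumerate(q):
            out.append((qk, r, k))
        hom -= q[0]
    if hom != 0.0:
        out.append((hom, decay, 0))
    return ExpSum(tuple(out))


def first_order_open(config: ModelConfig) -> ExpSum:
    """The first-order open fraction ``y_1(t)`` as an explicit three-term sum.

    .. math::

        y_1(t) = \\frac{A k_b k_o}{S P} e^{-\\omega t}
               + \\frac{A k_b k_o}{R P} e^{-(P+\\omega) t}
               - \\frac{A k_b k_o}{R S} e^{-k_c t}

    with boundary conditions ``x_1(0) = y_1(0) = 0``; the coefficients sum to
    zero because ``R + S = P``.  If any of S, P, R is (near) zero the explicit
    form is singular and the function falls back to the generic cascade solve,
    which handles the coincidence through its resonant branch.
    """
    c = FirstOrderConstants.from_config(config)
    r, pulse = config.rates, config.pulse
    scale = abs(r.k_c) + abs(r.k_d) + abs(r.k_o) + abs(r.k_u) + abs(pulse.omega)
    if min(abs(c.S), abs(c.P), abs(c.R)) <= 1e3 * RESONANCE_RTOL * scale:
        # rate coincidence: derive the same function by the cascade instead
        forcing = ExpSum.exponential(r.k_b * pulse.A, pulse.omega)
        x1 = solve_linear_exp_ode(forcing, r.k_o + r.k_u + r.k_d)
        return solve_linear_exp_ode(r.k_o * x1, r.k_c)
    amp = pulse.A * r.k_b * r.k_o
    return ExpSum(
        (
            (amp / (c.S * c.P), pulse.omega, 0),
            (amp / (c.R * c.P), c.P + pulse.omega, 0),
            (-amp / (c.R * c.S), r.k_c, 0),
        )
    )


def solve_scheme2(config: ModelConfig) -> List[OrderSolution]:
    """Closed-form trajectories of all ``config.n_orders`` meshes.

    Order 1 is driven with ``lambda_1 = 1``; order ``i`` is driven by the
    previous order's bound fraction, ``k_b A exp(-omega t) x_{i-1}(t)``.  The
    desensitized fraction obeys ``z_i' = k_d x_i - k_r z_i`` with
    ``z_i(0) = 0``, the only form consistent with the mesh's ``D_i ->
    C_{i-1}`` exit.
    """
    r, pulse = config.rates, config.pulse
    K = r.k_o + r.k_u + r.k_d
    lam = ExpSum.constant(1.0)
    base = ExpSum.exponential(r.k_b * pulse.A, pulse.omega)
    solutions: List[OrderSolution] = []
    for order in range(1, config.n_orders + 1):
        forcing = base * lam
        x = solve_linear_exp_ode(forcing, K)
        y = solve_linear_exp_ode(r.k_o * x, r.k_c)
        z = solve_linear_exp_ode(r.k_d * x, r.k_r)
        solutions.append(OrderSolution(order=order, x=x, y=y, z=z, lambda_source=lam))
        lam = x
    return solutions


@dataclass(frozen=True)
class Conductance:
    """Weighted synaptic conductance, callable at scalar times or grids."""

    expsum: ExpSum

    def __call__(self, t):
        return self.expsum(t)


def conductance(solutions: Sequence[OrderSolution], config: ModelConfig) -> Conductance:
    """Total conductance ``g(t) = nu * g4 * sum_i a_i y_i(t)``.

    Only open states conduct; each order contributes a fraction ``a_i`` of the
    fully-bound open-state conductance ``g4``, and ``nu`` renormalizes the
    analytical state fractions to absolute channel fractions.
    """
    if not solutions:
        raise ValueError("at least one order solution is required")
    total = ExpSum.zero()
    for sol in solutions:
        total = total + config.weights.a[sol.order - 1] * sol.y
    return Conductance(expsum=(config.nu * config.weights.g4) * total)


def temperature_conductance(config: ModelConfig, T: float) -> Conductance:
    """Closed-form conductance with rates rescaled to temperature ``T``."""
    cfg = scale_config(config, T)
    return conductance(solve_scheme2(cfg), cfg)
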