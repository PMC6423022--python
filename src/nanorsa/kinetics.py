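"""Adsorption kinetics: the coverage ODE, isotherms, and diffusion timescales.

The mean-field kinetics of irreversible-ish adsorption are

    d theta / dt = k_a n B(theta) - k_d theta

with adsorption rate ``k_a`` (L mol^-1 s^-1), desorption rate ``k_d``
(s^-1) and constant bulk concentration ``n`` (mol/L) — adsorption is
assumed not to deplete the bulk.  The Langmuir model is the special case
``B = theta_inf - theta``, whose steady state is the closed-form isotherm

    theta = K_eq n / (1 + K_eq n) * theta_inf,       K_eq = k_a / k_d.

An RSA blocking function (simulated and fitted as a cubic) replaces the
Langmuir ``B`` to produce kinetics and isotherms that respect surface
exclusion.  The closed-form diffusion timescale

    h = 1 / (n sigma),        tau_D = h^2 / D_dif = 1 / (n^2 sigma^2 D_dif)

(with ``n`` in molecules/m^3 and ``sigma`` in m^2) bounds the regime where
the adsorption step, not transport, limits the kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .engine import ProteinModel

__all__ = [
    "KineticsSpec",
    "BlockingPolynomial",
    "LangmuirBlocking",
    "Trajectory",
    "TimescaleEstimate",
    "solve_kinetics",
    "langmuir_isotherm",
    "rsa_isotherm",
    "diffusion_timescale",
]


@dataclass(frozen=True)
class KineticsSpec:
    """Rate constants and bulk concentration.

    Defaults are the albumin literature values ``k_a = 1e4 L mol^-1 s^-1``
    and ``k_d = 5.78e-4 s^-1`` (so ``K_eq = k_a/k_d ~ 1.73e7 L/mol``).
    """

    n: float
    k_a: float = 1.0e4
    k_d: float = 5.78e-4

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_d < 0 or self.n < 0:
            raise ValueError("rates and concentration must be non-negative")

    @property
    def K_eq(self) -> float:
        """Equilibrium constant ``k_a / k_d`` in L/mol."""
        if self.k_d == 0:
            raise ZeroDivisionError("K_eq undefined for k_d = 0")
        return self.k_a / self.k_d


class BlockingPolynomial:
    """A fitted blocking polynomial, clamped to its physical branch.

    ``coeffs`` are ascending powers with ``coeffs[0] = B(0)`` (normally 1).
    Beyond the fitted range a cubic may go negative or turn back up, so the
    jamming limit ``theta_inf`` is defined as the smallest positive root
    and ``B`` is clamped to zero there and to ``max(poly, 0)`` below.
    """

    def __init__(self, coeffs):
        self.coeffs = tuple(float(c) for c in coeffs)
        roots = np.roots(self.coeffs[::-1])
        real = roots[np.abs(roots.imag) < 1e-9].real
        pos = real[(real > 0.0) & (real <= 1.0)]
        if pos.size == 0:
            raise ValueError("blocking polynomial has no root in (0, 1]; "
                             "cannot define a jamming limit")
        self.theta_inf = float(pos.min())

    def __call__(self, theta):
        th = np.asarray(theta, float)
        val = np.zeros_like(th)
        for c in self.coeffs[::-1]:
            val = val * th + c
        out = np.where(th >= self.theta_inf, 0.0, np.maximum(val, 0.0))
        return float(out) if np.isscalar(theta) else out


class LangmuirBlocking:
    """The Langmuir blocking function ``B = theta_inf - theta``."""

    def __init__(self, theta_inf: float):
        self.theta_inf = float(theta_inf)

    def __call__(self, theta):
        th = np.asarray(theta, float)
        out = np.maximum(self.theta_inf - th, 0.0)
        return float(out) if np.isscalar(theta) else out


@dataclass(frozen=True)
class Trajectory:
    """Coverage versus time with the long-time plateau."""

    t: np.ndarray
    theta: np.ndarray
    plateau: float


def _as_blocking(blocking):
    if callable(blocking):
        return blocking
    coeffs, theta_inf = blocking
    b = BlockingPolynomial(coeffs)
    if theta_inf is not None:
        b.theta_inf = float(theta_inf)
    return b


def solve_kinetics(spec: KineticsSpec, blocking, t_end: float,
                   n_points: int = 400) -> Trajectory:
    """Integrate the coverage ODE from an empty surface.

    ``blocking`` is a :class:`BlockingPolynomial`, :class:`LangmuirBlocking`
    or ``(coeffs, theta_inf)`` pair.  Adaptive integration at relative
    tolerance 1e-8; the returned plateau is the final coverage value.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    B = _as_blocking(blocking)
    kan = spec.k_a * spec.n

    def rhs(t, y):
        return [kan * B(y[0]) - spec.k_d * y[0]]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=t_eval,
                    method="LSODA", rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    theta = np.clip(sol.y[0], 0.0, None)
    return Trajectory(sol.t, theta, float(theta[-1]))


def langmuir_isotherm(spec: KineticsSpec, theta_inf: float, n=None):
    """Closed-form Langmuir steady state ``K n/(1 + K n) theta_inf``.

    ``n`` defaults to ``spec.n``; an array gives the full isotherm.
    """
    conc = spec.n if n is None else np.asarray(n, float)
    Kn = spec.K_eq * conc
    out = Kn / (1.0 + Kn) * theta_inf
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def rsa_isotherm(spec: KineticsSpec, blocking, n=None):
    """Steady state of the coverage ODE, ``k_a n B(theta) = k_d theta``.

    Solved by bracketed root finding on ``[0, theta_inf]`` for each
    concentration; requires ``k_d > 0`` (otherwise every concentration
    saturates at the jamming limit).
    """
    if spec.k_d <= 0:
        raise ValueError("rsa_isotherm requires k_d > 0")
    B = _as_blocking(blocking)
    conc = spec.n if n is None else n
    arr = np.atleast_1d(np.asarray(conc, float))
    out = np.empty(arr.shape)
    for i, c in enumerate(arr):
        if c <= 0.0:
            out[i] = 0.0
            continue
        def f(th, c=c):
            return spec.k_a * c * B(th) - spec.k_d * th
        hi = B.theta_inf
        if f(hi) >= 0.0:
            out[i] = hi
        else:
            out[i] = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return float(out[0]) if np.isscalar(conc) else out.reshape(np.shape(conc))


@dataclass(frozen=True)
class TimescaleEstimate:
    """Near-surface interaction length ``h`` (m), diffusion time ``tau_D`` (s),
    and optionally the adsorption timescale ``tau_a`` (s)."""

    h: float
    tau_D: float
    tau_a: float | None = None


def diffusion_timescale(protein: ProteinModel, n: float,
                        spec: KineticsSpec | None = None,
                        blocking=None) -> TimescaleEstimate:
    """Closed-form diffusion timescale for bulk concentration ``n`` (mol/L).

    Converts ``n`` to molecules/m^3 and the cross-section to m^2, then
    ``h = 1/(n sigma)`` and ``tau_D = h^2 / D_dif``.  If a kinetics spec
    and blocking function are supplied, ``tau_a`` is reported as the time
    for the coverage to reach 99% of its plateau.
    """
    if n <= 0:
        raise ValueError("concentration must be positive")
    n_m3 = n * 1000.0 * Avogadro
    sigma_m2 = math.pi * (protein.D * 1e-9) ** 2 / 4.0
    h = 1.0 / (n_m3 * sigma_m2)
    tau_D = h * h / protein.D_dif
    tau_a = None
    if spec is not None and blocking is not None:
        spec_n = KineticsSpec(n=n, k_a=spec.k_a, k_d=spec.k_d)
        # integrate long enough to be safely past the plateau knee
        t_end = 50.0 / (spec.k_a * n)
        traj = solve_kinetics(spec_n, blocking, t_end, n_points=4000)
        target = 0.99 * traj.plateau
        above = np.nonzero(traj.theta >= target)[0]
        tau_a = float(traj.t[above[0]]) if above.size else float("inf")
    return TimescaleEstimate(h, tau_D, tau_a)
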