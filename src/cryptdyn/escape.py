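"""Closed-form analysis of the unbounded-growth (escape) regime.

Once the differentiation feedback saturates at ``delta_max < beta``, the
dynamics become linear::

    dS/dt = (beta - delta_max) S
    dD/dt = delta_max S - omega D

with exact solution

    S(t) = S0 * exp(b t),                      b = beta - delta_max
    D(t) = (D0 - A) * exp(-omega t) + A * exp(b t),
    A = S0 * delta_max / (b + omega).

(The commonly quoted form of ``D(t)`` drops the lower-limit term of the
convolution integral and therefore misses ``D(0) = D0``; the decaying
correction ``-A exp(-omega t)`` restores it without changing any
asymptotics.)  The stem-to-differentiated ratio converges to
``(beta + omega)/delta_max - 1`` and the total population grows like
``S0 * (beta + omega)/(beta + omega - delta_max) * exp(b t)``.

With dedifferentiation saturating at ``rho_min``, the limiting ratio
generalises to ``(a + b + w) / (2 delta_max)`` with
``a = sqrt(4 delta_max rho_min + (b + w)^2)``, ``b = beta - delta_max``,
``w = omega + rho_min``; at ``rho_min = 0`` this reduces exactly to the
basic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .simulate import Trajectory

__all__ = [
    "EscapeReport",
    "WrongRegimeError",
    "closed_form_trajectory",
    "limit_ratio",
    "limit_ratio_dediff",
    "saturating_topology_limit_ratio",
    "escape_report",
    "measured_growth_rate",
]


class WrongRegimeError(ValueError):
    """The requested closed form only applies in the unbounded-growth regime."""


@dataclass
class EscapeReport:
    """Summary of the saturated, exponentially growing regime."""

    growth_rate: float           # beta - delta_max
    limit_ratio: float           # lim S/D
    prefactor: float             # (beta+omega)/(beta+omega-delta_max)
    S_closed_form: Callable[[float], float]
    D_closed_form: Callable[[float], float]


def _check_regime(beta: float, delta_max: float) -> None:
    if not beta > delta_max:
        raise WrongRegimeError(
            f"escape analysis requires beta > delta_max "
            f"(got beta={beta}, delta_max={delta_max}); below the threshold "
            "a non-trivial steady state exists instead")


def closed_form_trajectory(beta: float, omega: float, delta_max: float,
                           S0: float, D0: float,
                           ) -> tuple[Callable, Callable]:
    """Exact ``(S(t), D(t))`` of the saturated linear system (vectorised in t)."""
    _check_regime(beta, delta_max)
    b = beta - delta_max
    A = S0 * delta_max / (b + omega)

    def S(t):
        return S0 * np.exp(b * np.asarray(t, dtype=float))

    def D(t):
        t = np.asarray(t, dtype=float)
        return (D0 - A) * np.exp(-omega * t) + A * np.exp(b * t)

    return S, D


def limit_ratio(beta: float, omega: float, delta_max: float) -> float:
    """Limiting stem-to-differentiated ratio ``(beta + omega)/delta_max - 1``."""
    _check_regime(beta, delta_max)
    return (beta + omega) / delta_max - 1.0


def limit_ratio_dediff(beta: float, omega: float, delta_max: float,
                       rho_min: float) -> float:
    """Limiting ratio with dedifferentiation floored at ``rho_min``."""
    if rho_min < 0:
        raise ValueError("rho_min must be non-negative")
    b = beta - delta_max
    w = omega + rho_min
    a = math.sqrt(4.0 * delta_max * rho_min + (b + w) ** 2)
    ratio = (a + b + w) / (2.0 * delta_max)
    if ratio <= 0:
        raise WrongRegimeError(
            "parameters do not produce a growing stem compartment "
            "(system is not in the unbounded-growth regime)")
    return ratio


def saturating_topology_limit_ratio(beta_min: float, omega: float,
                                    delta_max: float) -> float:
    """Limiting ratio for any topology whose stem-cell rates saturate.

    When proliferation saturates to a floor ``beta_min`` and
    differentiation to a ceiling ``delta_max`` with ``beta_min >
    delta_max``, growth escapes and the ratio converges to
    ``(beta_min + omega)/delta_max - 1`` by the same algebra as the basic
    case.
    """
    _check_regime(beta_min, delta_max)
    return (beta_min + omega) / delta_max - 1.0


def escape_report(beta: float, omega: float, delta_max: float,
                  S0: float = 1.0, D0: float = 0.0) -> EscapeReport:
    """Bundle growth rate, limiting ratio, prefactor and closed forms."""
    S, D = closed_form_trajectory(beta, omega, delta_max, S0, D0)
    return EscapeReport(
        growth_rate=beta - delta_max,
        limit_ratio=limit_ratio(beta, omega, delta_max),
        prefactor=(beta + omega) / (beta + omega - delta_max),
        S_closed_form=S,
        D_closed_form=D,
    )


def measured_growth_rate(traj: Trajectory, tail_fraction: float = 0.25) -> float:
    """Exponential escape rate from a log-linear fit on the trajectory tail.

    Unbounded-growth runs are capped in time; the asymptotic rate is
    estimated from ``log S(t)`` over the final ``tail_fraction`` of the run
    rather than by integrating towards overflow.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    n = max(2, int(len(traj) * tail_fraction))
    t = traj.t[-n:]
    S = traj.S[-n:]
    if np.any(S <= 0):
        raise WrongRegimeError("stem compartment is not growing")
    slope, _ = np.polyfit(t, np.log(S), 1)
    return float(slope)
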