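"""Steady states, Jacobians, stability classes and oscillation metrics.

For the basic crypt model the non-trivial steady state sits at
``D_bar = delta^{-1}(beta)`` and ``S_bar = omega * D_bar / beta``; it
exists iff the differentiation rate can reach the stem-cell growth rate,
and by the Routh-Hurwitz criterion it is stable iff
``0 < delta'(D_bar) < delta(D_bar) / D_bar``.  The trivial (extinct)
state ``(0, 0)`` always exists and is stable iff ``beta < delta(0)``.

With dedifferentiation, the steady state solves

    beta - delta((beta/omega) S_bar) + (beta/omega) rho(S_bar) = 0

with ``D_bar = beta * S_bar / omega``; a sufficiently strong ``rho`` can
destroy this root, opening a second route to unbounded growth.

Four regimes are distinguished: ``homeostasis`` (stable non-trivial
state), ``extinction`` (stable trivial state), ``unbounded_growth`` (no
non-trivial state, unstable trivial state) and ``sustained_oscillation``
(oscillatory non-trivial state with positive real part).
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .feedback import Feedback, NoPreimageError
from .model import ModelSpec, with_parameter

__all__ = [
    "EquilibriumReport",
    "OscillationMetrics",
    "InfeasibleParameterError",
    "NotAFocusError",
    "steady_states",
    "jacobian_at",
    "classify_eigenvalues",
    "eigenvalues_piecewise_linear",
    "node_focus_discriminant",
    "oscillation_metrics",
    "rho0_critical",
    "bifurcation_scan",
]

#: |Re(lambda)| below ``MARGINAL_FACTOR * max(beta-scale, omega-scale)``
#: classifies as 'marginal' -- a guard against floating-point sign tests
#: near stability boundaries.
MARGINAL_FACTOR = 1e-9


class InfeasibleParameterError(ValueError):
    """Parameters violate a feasibility condition of the requested formula."""


class NotAFocusError(ValueError):
    """Oscillation metrics were requested for a non-oscillatory state."""


@dataclass
class EquilibriumReport:
    """One steady state with its local linearisation and classification."""

    kind: str                      # 'trivial' | 'nontrivial'
    S_bar: float
    D_bar: float
    jacobian: np.ndarray           # 2x2, entries in 1/time
    eigenvalues: tuple[complex, complex]   # sorted by descending real part
    stability: str                 # stable_node | stable_focus | unstable | marginal
    regime: str                    # homeostasis | extinction | unbounded_growth
                                   # | sustained_oscillation
    decay_rate: float              # Re(lambda) of the slow mode
    angular_frequency: float       # |Im(lambda)| (0 for nodes)
    at_kink: bool = False          # Jacobian used a one-sided derivative

    @property
    def is_stable(self) -> bool:
        return self.stability in ("stable_node", "stable_focus")


@dataclass
class OscillationMetrics:
    """Damped-oscillation metrics of a stable focus.

    ``angular_frequency`` is |Im(lambda)| of the steady-state Jacobian --
    the canonical value.  For the piecewise-linear crypt model an
    alternative closed-form frequency expression,
    ``sqrt(delta_slope * D_bar * (4 beta^2 omega + omega^2) - beta omega^2)
    / (2 beta)``, is also evaluated; it does not reduce to |Im(lambda)|
    under the steady-state substitution ``delta_0 = beta - delta_slope *
    D_bar``, so it is reported alongside with a consistency flag rather
    than silently reconciled.
    """

    decay_rate: float
    angular_frequency: float
    angular_frequency_alt: Optional[float] = None
    alt_consistent: Optional[bool] = None


# ----------------------------------------------------------------- Jacobian

def jacobian_at(spec: ModelSpec, S: float, D: float,
                return_kink: bool = False):
    """Analytic Jacobian of the RHS at ``(S, D)``.

    Uses the feedback functions' analytic derivatives; at a clamp kink the
    left-hand derivative is used and the kink flag is set (retrieve it with
    ``return_kink=True``).
    """
    if S < 0 or D < 0:
        raise ValueError("state must be non-negative")
    b = spec.beta_at(S, D)
    d = spec.delta_at(S, D)
    w = spec.omega_at(S, D)
    reg = S if spec.regulator == "S" else D
    kink = False

    db_dS = db_dD = dd_dS = dd_dD = dw_dS = dw_dD = 0.0
    rate = spec.regulated_rate
    fb: Feedback = getattr(spec, rate)
    deriv, is_kink = fb.derivative_info(reg)
    kink |= is_kink
    if rate == "beta":
        if spec.regulator == "S":
            db_dS = deriv
        else:
            db_dD = deriv
    elif rate == "delta":
        if spec.regulator == "S":
            dd_dS = deriv
        else:
            dd_dD = deriv
    else:
        if spec.regulator == "S":
            dw_dS = deriv
        else:
            dw_dD = deriv

    r = rp = 0.0
    if spec.rho is not None:
        r = spec.rho.value(S)
        rp, rho_kink = spec.rho.derivative_info(S)
        kink |= rho_kink

    J = np.array([
        [b - d + (db_dS - dd_dS) * S + rp * D,
         (db_dD - dd_dD) * S + r],
        [d + dd_dS * S - rp * D - dw_dS * D,
         dd_dD * S - r - w - dw_dD * D],
    ])
    if return_kink:
        return J, kink
    return J


# ----------------------------------------------------------- classification

def _rate_scale(spec: ModelSpec) -> float:
    vals = []
    for name in ("beta", "omega"):
        v = getattr(spec, name)
        if isinstance(v, Feedback):
            vals.append(max(abs(x) for x in (v.range[0], v.range[1])
                            if math.isfinite(x)) or 1.0)
        else:
            vals.append(abs(v))
    return max(vals)


def classify_eigenvalues(eigenvalues, tol: float) -> str:
    """Map an eigenvalue pair to a stability class.

    ``stable_node``: real pair, both negative; ``stable_focus``: complex
    pair with negative real part; ``unstable``: any real part above +tol;
    ``marginal``: |Re| within tol of zero.
    """
    res = [complex(ev).real for ev in eigenvalues]
    ims = [complex(ev).imag for ev in eigenvalues]
    if any(re > tol for re in res):
        return "unstable"
    if any(abs(re) <= tol for re in res):
        return "marginal"
    if any(abs(im) > 0 for im in ims):
        return "stable_focus"
    return "stable_node"


def _sorted_eigs(J: np.ndarray) -> tuple[complex, complex]:
    eigs = np.linalg.eigvals(J)
    order = np.argsort(-eigs.real)
    return complex(eigs[order[0]]), complex(eigs[order[1]])


def _report(spec: ModelSpec, kind: str, S_bar: float, D_bar: float,
            regime: str = "") -> EquilibriumReport:
    J, kink = jacobian_at(spec, S_bar, D_bar, return_kink=True)
    eigs = _sorted_eigs(J)
    tol = MARGINAL_FACTOR * _rate_scale(spec)
    stability = classify_eigenvalues(eigs, tol)
    slow = eigs[0]
    return EquilibriumReport(
        kind=kind, S_bar=S_bar, D_bar=D_bar, jacobian=J, eigenvalues=eigs,
        stability=stability, regime=regime, decay_rate=slow.real,
        angular_frequency=abs(slow.imag), at_kink=kink)


# ------------------------------------------------------------ steady states

def _nontrivial_states(spec: ModelSpec) -> list[tuple[float, float]]:
    """All biologically feasible (S_bar > 0, D_bar > 0) non-trivial states."""
    rate = spec.regulated_rate
    if rate == "omega":
        # dS/dt = (beta - delta) S vanishes identically only if beta == delta;
        # no isolated non-trivial state exists.
        return []
    if spec.rho is not None:
        return _dediff_states(spec)
    if rate == "delta":
        fb: Feedback = spec.delta
        beta = spec.beta
        if not fb.in_range(beta):
            return []
        reg_bar = fb.inverse(beta)
        if spec.regulator == "D":
            D_bar = reg_bar
            S_bar = spec.omega * D_bar / beta
        else:
            S_bar = reg_bar
            D_bar = beta * S_bar / spec.omega
    else:  # beta regulated
        fb = spec.beta
        delta = spec.delta
        if not fb.in_range(delta):
            return []
        reg_bar = fb.inverse(delta)
        if spec.regulator == "D":
            D_bar = reg_bar
            S_bar = spec.omega * D_bar / delta
        else:
            S_bar = reg_bar
            D_bar = delta * S_bar / spec.omega
    if S_bar > 0 and D_bar > 0:
        return [(S_bar, D_bar)]
    return []


def _dediff_states(spec: ModelSpec) -> list[tuple[float, float]]:
    """Roots of  beta - delta((beta/omega) S) + (beta/omega) rho(S) = 0.

    Bracketed scalar search on a grid extending past the saturation points
    of both feedbacks (beyond which the residual is constant); all sign
    changes are refined with Brent's method and every root is reported.
    Tangency roots (a double root at loss of homeostasis) may be missed by
    sign-change detection; see the package methods note.
    """
    beta, omega = spec.beta, spec.omega
    k = beta / omega

    def g(S: float) -> float:
        return beta - spec.delta.value(k * S) + k * spec.rho.value(S)

    S_hi = 1.0
    for fb, scale in ((spec.delta, 1.0 / k), (spec.rho, 1.0)):
        start = fb.saturation_start
        if start is not None:
            S_hi = max(S_hi, 1.5 * start * scale)
    # if a feedback never saturates, extend until the residual is decisive
    for _ in range(60):
        if spec.delta.saturation_start is not None or g(S_hi) < 0:
            break
        S_hi *= 2.0
    grid = np.linspace(0.0, S_hi, 2001)[1:]
    vals = np.array([g(s) for s in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(g, grid[i], grid[i + 1], xtol=1e-12,
                                      rtol=1e-14)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # deduplicate near-identical roots
    out: list[tuple[float, float]] = []
    for S_bar in roots:
        if out and abs(S_bar - out[-1][0]) < 1e-9 * max(1.0, S_bar):
            continue
        out.append((S_bar, k * S_bar))
    return out


def _system_regime(spec: ModelSpec, trivial: EquilibriumReport,
                   nontrivial: list[EquilibriumReport]) -> str:
    if nontrivial:
        if any(r.is_stable for r in nontrivial):
            return "homeostasis"
        if any(abs(r.eigenvalues[0].imag) > 0 and r.stability == "unstable"
               for r in nontrivial):
            return "sustained_oscillation"
        if any(r.stability == "marginal" for r in nontrivial):
            # e.g. the delta_0 = 0 conservative (Lotka-Volterra) limit
            return "sustained_oscillation"
        return "unbounded_growth"
    # only the extinct state remains
    if trivial.stability in ("stable_node", "stable_focus", "marginal"):
        return "extinction"
    return "unbounded_growth"


def steady_states(spec: ModelSpec) -> list[EquilibriumReport]:
    """All steady states of the model, classified, trivial state first.

    Every report carries the same system-level ``regime`` label.
    """
    trivial = _report(spec, "trivial", 0.0, 0.0)
    nontrivial = [_report(spec, "nontrivial", S, D)
                  for S, D in _nontrivial_states(spec)]
    regime = _system_regime(spec, trivial, nontrivial)
    trivial.regime = regime
    for r in nontrivial:
        r.regime = regime
    return [trivial] + nontrivial


# ------------------------------------------------- closed forms (pw linear)

def node_focus_discriminant(beta: float, omega: float, delta0: float) -> float:
    """Radicand of the eigenvalue formula for linear feedback.

    ``-4 beta^3 omega + 4 beta^2 delta0 omega + delta0^2 omega^2``;
    positive -> stable node, negative -> stable focus.  Equivalently the
    node condition reads ``beta - delta0 < delta0^2 omega / (4 beta^2)``.
    """
    return (-4.0 * beta**3 * omega + 4.0 * beta**2 * delta0 * omega
            + delta0**2 * omega**2)


def eigenvalues_piecewise_linear(beta: float, omega: float,
                                 delta0: float) -> tuple[complex, complex]:
    """Closed-form eigenvalues at the interior steady state, linear feedback.

    ``lambda_{1,2} = (-delta0 omega +/- sqrt(disc)) / (2 beta)`` with the
    discriminant of :func:`node_focus_discriminant`.  Requires the
    feasibility condition ``0 < delta0 < beta`` (the slope and the
    saturation bound drop out of the spectrum).
    """
    if not beta > 0 or not omega > 0:
        raise InfeasibleParameterError("beta and omega must be positive")
    if not delta0 < beta:
        raise InfeasibleParameterError(
            f"feasible interior steady state requires delta0 < beta "
            f"(got delta0={delta0}, beta={beta})")
    if not delta0 > 0:
        raise InfeasibleParameterError(
            "delta0 must be positive (delta0 = 0 is the conservative "
            "Lotka-Volterra limit with marginal eigenvalues)")
    disc = node_focus_discriminant(beta, omega, delta0)
    root = cmath.sqrt(disc)
    lam1 = (-delta0 * omega + root) / (2.0 * beta)
    lam2 = (-delta0 * omega - root) / (2.0 * beta)
    if lam1.real < lam2.real:
        lam1, lam2 = lam2, lam1
    return complex(lam1), complex(lam2)


def oscillation_metrics(spec: ModelSpec,
                        report: EquilibriumReport) -> OscillationMetrics:
    """Decay rate and angular frequency of damped oscillations at a focus.

    Raises :class:`NotAFocusError` for a node.  For the piecewise-linear
    crypt model the alternative closed-form frequency is evaluated as well
    (see :class:`OscillationMetrics`).
    """
    lam = report.eigenvalues[0]
    if abs(lam.imag) == 0.0:
        raise NotAFocusError("steady state is a node; no oscillation to measure")
    decay = lam.real
    freq = abs(lam.imag)
    alt = None
    consistent = None
    if (spec.regulated_rate == "delta" and spec.regulator == "D"
            and spec.rho is None
            and isinstance(spec.delta, Feedback)
            and spec.delta.shape in ("linear", "piecewise_linear")):
        beta, omega = spec.beta, spec.omega
        slope = spec.delta.slope
        D_bar = report.D_bar
        radicand = (slope * D_bar * (4.0 * beta**2 * omega + omega**2)
                    - beta * omega**2)
        if radicand >= 0:
            alt = math.sqrt(radicand) / (2.0 * beta)
            consistent = abs(alt - freq) <= 1e-9 * max(freq, 1e-30)
    return OscillationMetrics(decay_rate=decay, angular_frequency=freq,
                              angular_frequency_alt=alt,
                              alt_consistent=consistent)


def rho0_critical(beta: float, delta0: float, omega: float) -> float:
    """Dedifferentiation threshold ``(beta - delta0/2) * 4 omega^2 / beta^2``.

    For a dedifferentiation rate that is effectively constant near the
    steady state, a basal value above this threshold reduces the
    post-perturbation oscillation frequency relative to no
    dedifferentiation (below it, the frequency is slightly increased).
    """
    return (beta - delta0 / 2.0) * 4.0 * omega**2 / beta**2


# ------------------------------------------------------------------- scans

_SCAN_COLUMNS = ["parameter", "value", "S_bar", "D_bar",
                 "re_lambda1", "im_lambda1", "re_lambda2", "im_lambda2",
                 "stability", "regime"]


def bifurcation_scan(spec: ModelSpec, parameter: str, values) -> pd.DataFrame:
    """Steady states and regimes along a 1-D parameter grid.

    Each row reports the non-trivial state (NaN coordinates when it does
    not exist, in which case the eigenvalues shown are those of the trivial
    state) together with the stability class and system regime.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty parameter grid")
    rows = []
    for v in values:
        try:
            sp = with_parameter(spec, parameter, v)
        except ValueError as exc:
            raise
        reports = steady_states(sp)
        trivial, nontrivial = reports[0], reports[1:]
        rep = nontrivial[0] if nontrivial else trivial
        rows.append({
            "parameter": parameter,
            "value": float(v),
            "S_bar": rep.S_bar if nontrivial else math.nan,
            "D_bar": rep.D_bar if nontrivial else math.nan,
            "re_lambda1": rep.eigenvalues[0].real,
            "im_lambda1": rep.eigenvalues[0].imag,
            "re_lambda2": rep.eigenvalues[1].real,
            "im_lambda2": rep.eigenvalues[1].imag,
            "stability": rep.stability,
            "regime": rep.regime,
        })
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)
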