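"""Perturbation experiments and the recovery defect statistic chi.

After removing a fraction of one or both compartments from a stable
steady state, the tissue relaxes back.  Recovery quality is measured by
the *defect*::

    chi = integral over { t >= 0 : D(t) < D_bar } of  (D_bar - D(t)) dt

i.e. the cumulative shortfall of differentiated cells -- only intervals
where D is *below* its steady value count, since that is when tissue
function is lacking.  In the linear regime the defect is proportional to
the initial displacement, so cross-model comparisons are reported per
unit displacement (``Delta D(0)``, or ``Delta S(0)`` when only stem cells
are removed).

Two computations are provided: ``numerical`` (adaptive quadrature on the
dense simulated trajectory) and ``linearised`` (piecewise-analytic
integration of the relaxation written in the steady-state Jacobian's
eigenbasis), which serve as mutual cross-checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .equilibrium import EquilibriumReport, steady_states
from .model import ModelSpec
from .simulate import Trajectory, integrate
from .topology import matched_spec

__all__ = [
    "Perturbation",
    "DefectResult",
    "UnstableStateError",
    "defect_numerical",
    "defect_linearised",
    "defect_difference_map",
    "defect_range_table",
    "dediff_recovery_comparison",
    "RecoveryMetrics",
    "measure_frequency",
    "fit_decay_rate",
]

PERTURBATION_KINDS = ("remove_D", "remove_S", "remove_both")

#: integration of the defect stops once the deviation envelope has fallen
#: below ENVELOPE_TOL * D_bar
ENVELOPE_TOL = 1e-6


class UnstableStateError(ValueError):
    """Defects are only defined relative to a stable non-trivial state."""


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative removal of cells from the steady state at t = 0.

    ``remove_D``: D(0) = (1-f) D_bar;  ``remove_S``: S(0) = (1-f) S_bar;
    ``remove_both``: the same fraction is removed from both compartments.
    """

    kind: str
    fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")

    def initial_state(self, S_bar: float, D_bar: float) -> tuple[float, float]:
        f = self.fraction
        S0 = S_bar * (1.0 - f) if self.kind in ("remove_S", "remove_both") else S_bar
        D0 = D_bar * (1.0 - f) if self.kind in ("remove_D", "remove_both") else D_bar
        return S0, D0

    def displacement(self, S_bar: float, D_bar: float) -> tuple[float, float]:
        """Signed initial displacement ``(Delta S(0), Delta D(0))``."""
        S0, D0 = self.initial_state(S_bar, D_bar)
        return S0 - S_bar, D0 - D_bar

    def reference_displacement(self, S_bar: float, D_bar: float) -> float:
        """Normalisation for per-displacement defects.

        ``Delta S(0)`` magnitude for ``remove_S``, ``Delta D(0)`` magnitude
        otherwise (the combined perturbation is expressed in multiples of
        the differentiated-cell displacement).
        """
        if self.kind == "remove_S":
            return self.fraction * S_bar
        return self.fraction * D_bar


@dataclass
class DefectResult:
    chi: float                       # cells * time
    chi_per_displacement: float      # time
    method: str                      # 'linearised' | 'numerical'
    truncation_time: float
    perturbation: Perturbation
    n_intervals: int = 0             # sub-steady intervals that contributed


# ------------------------------------------------------------------ helpers

def stable_nontrivial_report(spec: ModelSpec) -> EquilibriumReport:
    reports = [r for r in steady_states(spec) if r.kind == "nontrivial"]
    stable = [r for r in reports if r.is_stable]
    if not stable:
        raise UnstableStateError(
            "model has no stable non-trivial steady state "
            f"(regime: {steady_states(spec)[0].regime})")
    return stable[0]


def _zero_result(pert: Perturbation, method: str) -> DefectResult:
    return DefectResult(chi=0.0, chi_per_displacement=0.0, method=method,
                        truncation_time=0.0, perturbation=pert)


# ---------------------------------------------------------------- numerical

def defect_numerical(spec: ModelSpec, pert: Perturbation, *,
                     envelope_tol: float = ENVELOPE_TOL,
                     rtol: float = 1e-9, atol: float = 1e-12) -> DefectResult:
    """Defect by simulation: quadrature of ``D_bar - D(t)`` below steady state.

    The infinite horizon is truncated at the time the linear decay envelope
    predicts deviations below ``envelope_tol * D_bar``, plus one
    oscillation period of margin; sub-steady intervals are located by sign
    changes of the dense output and refined with Brent's method.
    """
    rep = stable_nontrivial_report(spec)
    if pert.fraction == 0.0:
        return _zero_result(pert, "numerical")
    S_bar, D_bar = rep.S_bar, rep.D_bar
    y0 = pert.initial_state(S_bar, D_bar)
    dS0, dD0 = pert.displacement(S_bar, D_bar)
    disp = math.hypot(dS0, dD0)

    a = rep.decay_rate                       # slow-mode Re(lambda) < 0
    T = math.log(envelope_tol * D_bar / disp) / a
    period = 2.0 * math.pi / rep.angular_frequency if rep.angular_frequency else None
    T += period if period is not None else 0.25 * T
    # nonlinear transients can outlive the linear envelope prediction a bit
    T *= 1.25

    traj = integrate(spec, y0, T, rtol=rtol, atol=atol)

    def dev(t):
        return traj.sol(t)[1] - D_bar

    # sample finely enough to catch every half-period sign change
    n = 4000 if period is None else max(2000, int(40 * T / period))
    n = min(n, 200_000)
    ts = np.linspace(0.0, T, n)
    vals = traj.sol(ts)[1] - D_bar
    crossings = []
    for i in range(n - 1):
        if vals[i] == 0.0:
            crossings.append(ts[i])
        elif vals[i] * vals[i + 1] < 0:
            crossings.append(brentq(dev, ts[i], ts[i + 1], xtol=1e-12))
    bounds = [0.0] + crossings + [T]

    chi = 0.0
    n_int = 0
    for lo, hi in zip(bounds, bounds[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        if dev(mid) < 0:
            val, _ = quad(lambda t: D_bar - traj.sol(t)[1], lo, hi, limit=200)
            chi += val
            n_int += 1
    ref = pert.reference_displacement(S_bar, D_bar)
    return DefectResult(chi=chi, chi_per_displacement=chi / ref,
                        method="numerical", truncation_time=T,
                        perturbation=pert, n_intervals=n_int)


# --------------------------------------------------------------- linearised

def _linearised_deviation(J: np.ndarray, x0: np.ndarray):
    """Decompose the linear relaxation of Delta D(t).

    Returns ('focus', a, w, R, psi) with Delta D = R e^{at} cos(w t - psi),
    or ('node', lam1, lam2, d1, d2) with Delta D = d1 e^{lam1 t} + d2
    e^{lam2 t}, or None for a defective (non-diagonalisable) Jacobian.
    """
    eigs = np.linalg.eigvals(J)
    if abs(eigs[0].imag) > 0:
        a = float(eigs[0].real)
        w = abs(float(eigs[0].imag))
        P = float(x0[1])
        Q = (float((J @ x0)[1]) - a * P) / w
        R = math.hypot(P, Q)
        psi = math.atan2(Q, P)
        return ("focus", a, w, R, psi)
    vals, vecs = np.linalg.eig(J)
    lam1, lam2 = float(vals[0].real), float(vals[1].real)
    if abs(lam1 - lam2) <= 1e-9 * max(abs(lam1), abs(lam2), 1e-30):
        return None
    c = np.linalg.solve(vecs.real, x0)
    d1 = float(c[0] * vecs[1, 0].real)
    d2 = float(c[1] * vecs[1, 1].real)
    if lam1 < lam2:
        lam1, lam2, d1, d2 = lam2, lam1, d2, d1
    return ("node", lam1, lam2, d1, d2)


def defect_linearised(spec: ModelSpec, pert: Perturbation, *,
                      envelope_tol: float = ENVELOPE_TOL) -> DefectResult:
    """Defect from the relaxation linearised at the steady state.

    Focus case: the deviation is ``R e^{at} cos(wt - psi)``; the defect is
    a sum of analytic integrals over successive half-periods with negative
    deviation, truncated once the envelope ``R e^{at}`` falls below
    ``envelope_tol * D_bar``.  Node case: the two-exponential deviation
    changes sign at most once and the defect integrals are evaluated in
    closed form to infinity.  A defective Jacobian falls back to
    :func:`defect_numerical` with a warning.
    """
    rep = stable_nontrivial_report(spec)
    if pert.fraction == 0.0:
        return _zero_result(pert, "linearised")
    S_bar, D_bar = rep.S_bar, rep.D_bar
    x0 = np.array(pert.displacement(S_bar, D_bar))
    ref = pert.reference_displacement(S_bar, D_bar)
    decomp = _linearised_deviation(rep.jacobian, x0)
    if decomp is None:
        warnings.warn("defective Jacobian: falling back to the numerical "
                      "defect", RuntimeWarning, stacklevel=2)
        res = defect_numerical(spec, pert, envelope_tol=envelope_tol)
        return replace(res, method="numerical")

    if decomp[0] == "focus":
        _, a, w, R, psi = decomp
        if R == 0.0:
            return _zero_result(pert, "linearised")

        denom = a * a + w * w

        def F(t):
            """Antiderivative of R e^{at} cos(wt - psi)."""
            return (R * math.exp(a * t)
                    * (a * math.cos(w * t - psi) + w * math.sin(w * t - psi))
                    / denom)

        # deviation negative on w t - psi in (pi/2, 3pi/2) mod 2 pi
        t_stop = math.log(envelope_tol * D_bar / R) / a if R > envelope_tol * D_bar \
            else 0.0
        chi = 0.0
        n_int = 0
        k = math.floor((w * 0.0 - psi - math.pi / 2) / (2 * math.pi))
        while True:
            lo = (psi + math.pi / 2 + 2 * math.pi * k) / w
            hi = (psi + 3 * math.pi / 2 + 2 * math.pi * k) / w
            k += 1
            if hi <= 0:
                continue
            lo = max(lo, 0.0)
            if lo >= t_stop and n_int > 0:
                break
            contrib = -(F(hi) - F(lo))
            if contrib > 0:
                chi += contrib
                n_int += 1
            if lo > t_stop:
                break
        return DefectResult(chi=chi, chi_per_displacement=chi / ref,
                            method="linearised", truncation_time=t_stop,
                            perturbation=pert, n_intervals=n_int)

    _, lam1, lam2, d1, d2 = decomp

    def G(t):
        """Antiderivative of Delta D(t) = d1 e^{lam1 t} + d2 e^{lam2 t}."""
        return d1 / lam1 * math.exp(lam1 * t) + d2 / lam2 * math.exp(lam2 * t)

    G_inf = 0.0
    boundaries = [0.0]
    if d1 != 0.0 and d2 != 0.0 and d1 * d2 < 0:
        t_star = math.log(-d1 / d2) / (lam2 - lam1)
        if t_star > 0:
            boundaries.append(t_star)
    boundaries.append(math.inf)
    chi = 0.0
    n_int = 0
    for lo, hi in zip(boundaries, boundaries[1:]):
        mid = lo + 1.0 if math.isinf(hi) else 0.5 * (lo + hi)
        if d1 * math.exp(lam1 * mid) + d2 * math.exp(lam2 * mid) < 0:
            upper = G_inf if math.isinf(hi) else G(hi)
            chi += -(upper - G(lo))
            n_int += 1
    amp = abs(d1) + abs(d2)
    t_env = (math.log(envelope_tol * D_bar / amp) / lam1
             if amp > envelope_tol * D_bar else 0.0)
    return DefectResult(chi=chi, chi_per_displacement=chi / ref,
                        method="linearised", truncation_time=t_env,
                        perturbation=pert, n_intervals=n_int)


# ------------------------------------------------------- model comparisons

def defect_difference_map(topology_a: str, topology_b: str,
                          perturbation: Perturbation,
                          stem_fraction: float,
                          beta_values,
                          intercept_ratios,
                          *,
                          total: float = 1100.0,
                          method: str = "linearised") -> pd.DataFrame:
    """Pointwise defect difference ``chi_b - chi_a`` over a parameter grid.

    Only makes sense for two topologies sharing a parameter space; the two
    delta-regulated wirings share ``(beta, delta0)``, the two
    beta-regulated ones share ``(beta0, delta)``.  Each grid point
    parameterises both models to the same steady state (``stem_fraction``
    of ``total`` cells) and compares defects per unit displacement.

    ``intercept_ratios`` are the values of ``delta0 / beta`` (or ``delta /
    beta0``), kept strictly below 1 for feasibility.  Long-format columns:
    ``beta, delta0, chi_a, chi_b, diff``.
    """
    group_a = topology_a.split("_of_")[0]
    group_b = topology_b.split("_of_")[0]
    if group_a != group_b:
        raise ValueError(
            f"{topology_a} and {topology_b} have different free parameters "
            "and cannot be compared pointwise; compare defect ranges instead "
            "(defect_range_table)")
    compute = defect_linearised if method == "linearised" else defect_numerical
    rows = []
    for beta in np.asarray(beta_values, dtype=float):
        for r in np.asarray(intercept_ratios, dtype=float):
            intercept = r * beta
            kwargs = ({"beta": beta, "delta0": intercept} if group_a == "delta"
                      else {"beta0": beta, "delta": intercept})
            spec_a = matched_spec(topology_a, stem_fraction, total=total, **kwargs)
            spec_b = matched_spec(topology_b, stem_fraction, total=total, **kwargs)
            chi_a = compute(spec_a, perturbation).chi_per_displacement
            chi_b = compute(spec_b, perturbation).chi_per_displacement
            rows.append({"beta": beta, "delta0": intercept,
                         "chi_a": chi_a, "chi_b": chi_b,
                         "diff": chi_b - chi_a})
    return pd.DataFrame(rows, columns=["beta", "delta0", "chi_a", "chi_b", "diff"])


def defect_range_table(topology: str, perturbation: Perturbation,
                       stem_fraction: float,
                       primary_values,
                       intercept_ratios,
                       *,
                       total: float = 1100.0,
                       method: str = "linearised") -> pd.DataFrame:
    """Per-unit-displacement defects of one topology over its own grid.

    For topologies with incomparable parameter spaces only range-based
    comparison is meaningful; this returns the long-format table
    (``primary, intercept, chi``) whose ``chi`` column's min/max define the
    range.  ``primary`` is ``beta`` (delta-regulated) or ``beta0``
    (beta-regulated); ``intercept`` is ``delta0`` or ``delta``.
    """
    group = topology.split("_of_")[0]
    compute = defect_linearised if method == "linearised" else defect_numerical
    rows = []
    for p in np.asarray(primary_values, dtype=float):
        for r in np.asarray(intercept_ratios, dtype=float):
            intercept = r * p
            kwargs = ({"beta": p, "delta0": intercept} if group == "delta"
                      else {"beta0": p, "delta": intercept})
            spec = matched_spec(topology, stem_fraction, total=total, **kwargs)
            chi = compute(spec, perturbation).chi_per_displacement
            rows.append({"primary": p, "intercept": intercept, "chi": chi})
    return pd.DataFrame(rows, columns=["primary", "intercept", "chi"])


# --------------------------------------------- dedifferentiation comparison

@dataclass
class RecoveryMetrics:
    """Post-perturbation recovery summary for one model variant."""

    defect: DefectResult
    amplitude: float                 # max |D(t) - D_bar| over the transient
    frequency: Optional[float]       # zero-crossing angular frequency
    decay_rate: Optional[float]      # envelope fit on |D - D_bar| peaks


def measure_frequency(traj: Trajectory, D_bar: float, *,
                      amplitude_floor: float = 1e-2,
                      min_crossings: int = 3) -> Optional[float]:
    """Angular frequency from zero crossings of ``D(t) - D_bar``.

    Crossing times are refined on the dense output; the angular frequency
    is ``pi / mean(crossing interval)``.  Once the oscillation has decayed
    towards the solver's noise floor, spurious crossings appear, so only
    half-periods whose amplitude exceeds ``amplitude_floor`` times the
    peak deviation are used.  Returns None with fewer than three usable
    crossings.
    """
    dev = traj.D - D_bar
    idx = np.nonzero(dev[:-1] * dev[1:] < 0)[0]
    if len(idx) < min_crossings:
        return None
    times = []
    for i in idx:
        times.append(brentq(lambda t: traj.sol(t)[1] - D_bar,
                            traj.t[i], traj.t[i + 1], xtol=1e-10))
    floor = amplitude_floor * np.max(np.abs(dev))
    seg_amp = []
    for lo, hi in zip(idx[:-1], idx[1:]):
        seg_amp.append(np.max(np.abs(dev[lo:hi + 1])))
    gaps = [hi - lo for lo, hi, amp in zip(times, times[1:], seg_amp)
            if amp >= floor]
    if len(gaps) < max(1, min_crossings - 1):
        return None
    return float(math.pi / np.mean(gaps))


def fit_decay_rate(traj: Trajectory, D_bar: float) -> Optional[float]:
    """Exponential decay rate of the |D - D_bar| oscillation envelope.

    Fits a line to log of the local maxima of the absolute deviation;
    returns None with fewer than three peaks.
    """
    dev = np.abs(traj.D - D_bar)
    peaks = [(traj.t[i], dev[i]) for i in range(1, len(dev) - 1)
             if dev[i] >= dev[i - 1] and dev[i] > dev[i + 1] and dev[i] > 0]
    if len(peaks) < 3:
        return None
    t = np.array([p[0] for p in peaks])
    v = np.array([p[1] for p in peaks])
    slope, _ = np.polyfit(t, np.log(v), 1)
    return float(slope)


def dediff_recovery_comparison(spec_without: ModelSpec, spec_with: ModelSpec,
                               pert: Perturbation, *,
                               t_end: Optional[float] = None,
                               ) -> tuple[RecoveryMetrics, RecoveryMetrics]:
    """Compare recovery with and without dedifferentiation.

    Both specs must share the same non-trivial steady state (the
    dedifferentiation rate must vanish there, so that rho only acts during
    the transient).  Returns numerically computed defects plus measured
    oscillation amplitude, zero-crossing frequency and envelope decay rate
    for each variant.
    """
    rep_a = stable_nontrivial_report(spec_without)
    rep_b = stable_nontrivial_report(spec_with)
    if (abs(rep_a.S_bar - rep_b.S_bar) > 1e-6 * rep_a.S_bar
            or abs(rep_a.D_bar - rep_b.D_bar) > 1e-6 * rep_a.D_bar):
        raise ValueError(
            "the two specs do not share a steady state "
            f"(({rep_a.S_bar:g}, {rep_a.D_bar:g}) vs "
            f"({rep_b.S_bar:g}, {rep_b.D_bar:g})); the comparison is only "
            "meaningful at a common operating point")
    out = []
    for spec, rep in ((spec_without, rep_a), (spec_with, rep_b)):
        res = defect_numerical(spec, pert)
        horizon = t_end if t_end is not None else res.truncation_time
        traj = integrate(spec, pert.initial_state(rep.S_bar, rep.D_bar),
                         horizon, rtol=1e-9, atol=1e-12,
                         t_eval=np.linspace(0, horizon, 4000))
        dev = np.abs(traj.D - rep.D_bar)
        out.append(RecoveryMetrics(
            defect=res,
            amplitude=float(dev.max()),
            frequency=measure_frequency(traj, rep.D_bar),
            decay_rate=fit_decay_rate(traj, rep.D_bar)))
    return out[0], out[1]
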