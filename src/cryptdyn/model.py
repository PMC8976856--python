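"""Model specification and ODE right-hand sides.

The tissue is described by two compartments: stem cells ``S`` with realised
growth rate ``beta`` that differentiate at rate ``delta``, and
differentiated cells ``D`` lost at apoptosis rate ``omega``.  Exactly one
of the three rates is regulated by exactly one compartment through a
:class:`~cryptdyn.feedback.Feedback`, which yields six one-loop topologies::

    dS/dt = beta(.) S - delta(.) S  [+ rho(S) D]
    dD/dt = delta(.) S - omega(.) D [- rho(S) D]

The crypt (colon) model is ``delta_of_D``: differentiated cells stimulate
stem-cell differentiation.  It is the only topology that optionally carries
a dedifferentiation term ``rho(S) D`` moving differentiated cells back into
the stem pool, with ``rho`` a decreasing function of ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

from .feedback import Feedback

__all__ = ["ModelSpec", "TOPOLOGIES", "rhs", "with_parameter"]

TOPOLOGIES = (
    "delta_of_D",   # crypt model: D stimulates differentiation
    "delta_of_S",   # S stimulates its own differentiation
    "beta_of_D",    # D inhibits stem-cell cycling
    "beta_of_S",    # S inhibits its own cycling
    "omega_of_S",   # S regulates apoptosis of D (not viable)
    "omega_of_D",   # D regulates its own apoptosis (not viable)
)

Rate = Union[float, Feedback]


def _rate_name(topology: str) -> str:
    return topology.split("_of_")[0]


def _regulator(topology: str) -> str:
    return topology.split("_of_")[1]


@dataclass(frozen=True)
class ModelSpec:
    """Topology plus all rate constants and feedback assignments.

    The regulated rate (named by ``topology``) must be a
    :class:`Feedback`; the other two rates must be positive constants.
    ``rho`` is only meaningful for the crypt model (``delta_of_D``) and
    must be a decreasing feedback of ``S``; ``rho=None`` gives the basic
    model.
    """

    topology: str = "delta_of_D"
    beta: Rate = 1.0
    omega: Rate = 0.1
    delta: Rate = 0.9
    rho: Optional[Feedback] = None

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        regulated = _rate_name(self.topology)
        for name in ("beta", "omega", "delta"):
            val = getattr(self, name)
            if name == regulated:
                if not isinstance(val, Feedback):
                    raise ValueError(
                        f"topology {self.topology}: {name} must be a Feedback")
            else:
                if isinstance(val, Feedback):
                    raise ValueError(
                        f"topology {self.topology}: {name} must be a constant rate")
                if not val > 0:
                    raise ValueError(f"{name} must be positive, got {val}")
        if regulated == "delta" and self.delta.direction != "increasing":
            raise ValueError("regulated delta must be an increasing feedback "
                             "(differentiation is stimulated)")
        if regulated == "beta" and self.beta.direction != "decreasing":
            raise ValueError("regulated beta must be a decreasing feedback "
                             "(stem-cell cycling is inhibited)")
        if self.rho is not None:
            if self.topology != "delta_of_D":
                raise ValueError("dedifferentiation is only defined for the "
                                 "crypt model (topology delta_of_D)")
            if not isinstance(self.rho, Feedback):
                raise ValueError("rho must be a Feedback")
            if self.rho.direction != "decreasing":
                raise ValueError("rho must be a decreasing function of S")

    # ------------------------------------------------------------ structure

    @property
    def regulated_rate(self) -> str:
        """Which rate carries the feedback: 'beta', 'delta' or 'omega'."""
        return _rate_name(self.topology)

    @property
    def regulator(self) -> str:
        """Which compartment drives the feedback: 'S' or 'D'."""
        return _regulator(self.topology)

    @property
    def has_dedifferentiation(self) -> bool:
        return self.rho is not None

    # ------------------------------------------------------- rate evaluation

    def _regulator_value(self, S: float, D: float) -> float:
        return S if self.regulator == "S" else D

    def beta_at(self, S: float, D: float) -> float:
        if isinstance(self.beta, Feedback):
            return self.beta.value(self._regulator_value(S, D))
        return self.beta

    def delta_at(self, S: float, D: float) -> float:
        if isinstance(self.delta, Feedback):
            return self.delta.value(self._regulator_value(S, D))
        return self.delta

    def omega_at(self, S: float, D: float) -> float:
        if isinstance(self.omega, Feedback):
            return self.omega.value(self._regulator_value(S, D))
        return self.omega

    def rho_at(self, S: float) -> float:
        if self.rho is None:
            return 0.0
        return self.rho.value(S)

    def rhs(self, S: float, D: float) -> tuple[float, float]:
        """Time derivatives ``(dS/dt, dD/dt)`` at state ``(S, D)``."""
        b = self.beta_at(S, D)
        d = self.delta_at(S, D)
        w = self.omega_at(S, D)
        r = self.rho_at(S) if self.rho is not None else 0.0
        dS = b * S - d * S + r * D
        dD = d * S - r * D - w * D
        return dS, dD


def rhs(spec: ModelSpec, S: float, D: float) -> tuple[float, float]:
    """Module-level convenience wrapper for :meth:`ModelSpec.rhs`."""
    return spec.rhs(S, D)


# --------------------------------------------------------- parameter access

_FEEDBACK_FIELDS = {"0": "intercept", "slope": "slope", "max": "saturation",
                    "min": "saturation", "mid": "midpoint", "p": "steepness"}


def _split_param(name: str) -> tuple[str, Optional[str]]:
    """Map a sweep-parameter name to (rate, feedback-field-or-None)."""
    for rate in ("beta", "delta", "omega", "rho"):
        if name == rate:
            return rate, None
        if name.startswith(rate):
            suffix = name[len(rate):].lstrip("_")
            if suffix in _FEEDBACK_FIELDS:
                return rate, _FEEDBACK_FIELDS[suffix]
    raise ValueError(f"unknown parameter name {name!r}")


def with_parameter(spec: ModelSpec, name: str, value: float) -> ModelSpec:
    """Return a copy of ``spec`` with one named parameter replaced.

    Recognised names: a bare rate (``beta``, ``omega``, ``delta``) for a
    constant rate, or ``<rate>0``, ``<rate>_slope``, ``<rate>_max`` /
    ``<rate>_min``, ``delta_mid``, ``delta_p`` for feedback fields (e.g.
    ``delta0``, ``delta_slope``, ``rho0``, ``beta_min``).
    """
    rate, fb_field = _split_param(name)
    current = getattr(spec, rate)
    if fb_field is None:
        if isinstance(current, Feedback):
            raise ValueError(
                f"{rate} is a regulated feedback; set e.g. {rate}0 instead")
        return replace(spec, **{rate: float(value)})
    if not isinstance(current, Feedback):
        raise ValueError(f"{rate} is a constant; cannot set its {fb_field}")
    return replace(spec, **{rate: replace(current, **{fb_field: float(value)})})
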