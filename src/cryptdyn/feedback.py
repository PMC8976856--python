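"""Monotone rate-modulating feedback functions.

In the two-compartment crypt model, per-cell rates are modulated by
compartment sizes: the stem-cell differentiation rate ``delta(D)`` increases
with the number of differentiated cells (BMP/Ihh-type signalling), the
dedifferentiation rate ``rho(S)`` decreases with the number of stem cells,
and in alternative wirings the stem-cell growth rate ``beta(.)`` is
inhibited by one of the compartments.

All of these are represented by :class:`Feedback`: a continuous, monotone
function on ``[0, inf)`` with an analytic derivative and an inverse defined
on the closure of the strictly monotone branch of its range.  Four shapes
are supported:

``linear``
    ``f(x) = intercept + slope * x`` (unbounded; ``slope`` may be 0, giving
    a constant rate).
``piecewise_linear``
    increasing: ``min(intercept + slope * x, saturation)`` with
    ``slope > 0``; decreasing: ``max(intercept + slope * x, saturation)``
    with ``slope < 0`` and ``saturation >= 0``.  The clamp point is a kink:
    the function is continuous but not differentiable there.
``sigmoidal``
    Hill-type ``intercept + saturation * x**p / (midpoint**p + x**p)``,
    bounded in ``[intercept, intercept + saturation)``.
``custom``
    user-supplied callables for value / derivative / inverse, validated for
    monotonicity on a sample grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Optional

__all__ = [
    "Feedback",
    "DomainError",
    "NoPreimageError",
    "linear",
    "piecewise_linear",
    "sigmoidal",
    "custom",
]

_SHAPES = ("linear", "piecewise_linear", "sigmoidal", "custom")
_DIRECTIONS = ("increasing", "decreasing")

#: x beyond which a custom function is considered saturated when probing
#: its range numerically.
_CUSTOM_RANGE_PROBE = 1e12


class DomainError(ValueError):
    """A feedback function was evaluated at a negative compartment size."""


class NoPreimageError(ValueError):
    """``inverse(y)`` was requested for a rate outside the function's range.

    Upstream this is the signal that a regulated rate can never reach the
    requested value -- e.g. the differentiation rate saturating below the
    stem-cell growth rate, which triggers unbounded growth.
    """


@dataclass(frozen=True)
class Feedback:
    """A monotone rate-modulating function of a compartment size.

    Parameters
    ----------
    shape:
        One of ``linear``, ``piecewise_linear``, ``sigmoidal``, ``custom``.
    intercept:
        Basal rate at ``x = 0`` (units 1/time).  For the sigmoidal shape
        this is the lower asymptote.
    slope:
        Linear response (1/(time*cells)); its sign encodes stimulation (+)
        versus inhibition (-).  Unused by the sigmoidal shape.
    saturation:
        Clamp value for the piecewise-linear shape (upper bound when
        increasing, lower bound when decreasing); amplitude of the Hill term
        for the sigmoidal shape.
    midpoint, steepness:
        Hill midpoint (cells) and exponent ``p`` (dimensionless); sigmoidal
        shape only.
    direction:
        Declared monotonicity, ``increasing`` or ``decreasing``.
    value_fn, derivative_fn, inverse_fn:
        Callables for the ``custom`` shape.
    """

    shape: str
    intercept: float = 0.0
    slope: float = 0.0
    saturation: Optional[float] = None
    midpoint: Optional[float] = None
    steepness: Optional[float] = None
    direction: str = "increasing"
    value_fn: Optional[Callable[[float], float]] = None
    derivative_fn: Optional[Callable[[float], float]] = None
    inverse_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown feedback shape {self.shape!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.shape == "linear":
            if self.slope > 0 and self.direction != "increasing":
                raise ValueError("positive slope requires direction='increasing'")
            if self.slope < 0 and self.direction != "decreasing":
                raise ValueError("negative slope requires direction='decreasing'")
        elif self.shape == "piecewise_linear":
            if self.saturation is None:
                raise ValueError("piecewise_linear requires a saturation bound")
            if self.direction == "increasing":
                if not self.slope > 0:
                    raise ValueError("increasing piecewise_linear requires slope > 0")
                if self.intercept < 0:
                    raise ValueError("intercept must be non-negative")
                if self.saturation < self.intercept:
                    raise ValueError("saturation below intercept for an increasing clamp")
            else:
                if not self.slope < 0:
                    raise ValueError("decreasing piecewise_linear requires slope < 0")
                if self.saturation < 0:
                    raise ValueError("saturation (floor) must be non-negative")
                if self.saturation > self.intercept:
                    raise ValueError("floor above intercept for a decreasing clamp")
        elif self.shape == "sigmoidal":
            if self.direction != "increasing":
                raise ValueError("sigmoidal shape is implemented increasing-only; "
                                 "use shape='custom' for a decreasing sigmoid")
            if self.saturation is None or self.midpoint is None or self.steepness is None:
                raise ValueError("sigmoidal requires saturation, midpoint and steepness")
            if self.saturation <= 0 or self.midpoint <= 0 or self.steepness <= 0:
                raise ValueError("sigmoidal parameters must be positive")
            if self.intercept < 0:
                raise ValueError("intercept must be non-negative")
        else:  # custom
            if self.value_fn is None:
                raise ValueError("custom shape requires value_fn")

    # ------------------------------------------------------------------ value

    def value(self, x: float) -> float:
        """Rate at compartment size ``x >= 0`` (1/time)."""
        x = float(x)
        if x < 0:
            raise DomainError(f"compartment size must be non-negative, got {x}")
        if self.shape == "linear":
            return self.intercept + self.slope * x
        if self.shape == "piecewise_linear":
            y = self.intercept + self.slope * x
            if self.direction == "increasing":
                return min(y, self.saturation)
            return max(y, self.saturation)
        if self.shape == "sigmoidal":
            if x == 0.0:
                return self.intercept
            p = self.steepness
            if x >= self.midpoint:
                # ratio form is overflow-safe for large x
                r = (self.midpoint / x) ** p
                return self.intercept + self.saturation / (1.0 + r)
            xp = x ** p                      # may underflow to 0 harmlessly
            mp = self.midpoint ** p
            return self.intercept + self.saturation * xp / (mp + xp)
        return float(self.value_fn(x))

    __call__ = value

    # ------------------------------------------------------------- derivative

    def derivative(self, x: float) -> float:
        """One-sided (left-hand at kinks) derivative at ``x``."""
        return self.derivative_info(x)[0]

    def derivative_info(self, x: float) -> tuple[float, bool]:
        """Derivative at ``x`` plus a flag marking a clamp kink.

        At the clamp point of a piecewise-linear shape the function is not
        differentiable; the left-hand derivative (the linear branch's slope)
        is returned and ``is_kink`` is True.
        """
        x = float(x)
        if x < 0:
            raise DomainError(f"compartment size must be non-negative, got {x}")
        if self.shape == "linear":
            return self.slope, False
        if self.shape == "piecewise_linear":
            kink = self.kink
            if x < kink:
                return self.slope, False
            if x == kink:
                return self.slope, True
            return 0.0, False
        if self.shape == "sigmoidal":
            p = self.steepness
            if x == 0.0:
                if p > 1.0:
                    return 0.0, False
                if p == 1.0:
                    return self.saturation / self.midpoint, False
                return math.inf, False
            mp = self.midpoint ** p
            xp = x ** p
            return self.saturation * p * mp * xp / (x * (mp + xp) ** 2), False
        if self.derivative_fn is not None:
            return float(self.derivative_fn(x)), False
        # central finite difference fallback for custom shapes
        h = 1e-6 * max(1.0, abs(x))
        lo = max(x - h, 0.0)
        return (self.value(x + h) - self.value(lo)) / (x + h - lo), False

    # ---------------------------------------------------------------- inverse

    def inverse(self, y: float) -> float:
        """Compartment size with ``value(x) == y``; exact on the monotone branch.

        Raises :class:`NoPreimageError` if ``y`` lies outside the closed
        range of the function over ``[0, inf)`` (for the sigmoidal shape the
        upper asymptote is never attained and has no preimage).
        """
        y = float(y)
        if self.shape == "linear":
            if self.slope == 0.0:
                raise NoPreimageError("constant function has no inverse")
            x = (y - self.intercept) / self.slope
            if x < 0:
                raise NoPreimageError(
                    f"rate {y} is outside the range of this feedback on [0, inf)")
            return x
        if self.shape == "piecewise_linear":
            lo, hi = self.range
            if not (lo <= y <= hi):
                raise NoPreimageError(
                    f"rate {y} is outside the feedback range [{lo}, {hi}]")
            if y == self.saturation:
                return self.kink
            return (y - self.intercept) / self.slope
        if self.shape == "sigmoidal":
            lo = self.intercept
            hi = self.intercept + self.saturation
            if not (lo <= y < hi):
                raise NoPreimageError(
                    f"rate {y} is outside the feedback range [{lo}, {hi})")
            if y == lo:
                return 0.0
            u = (y - lo) / self.saturation
            return self.midpoint * (u / (1.0 - u)) ** (1.0 / self.steepness)
        if self.inverse_fn is None:
            raise NoPreimageError("custom feedback has no inverse_fn")
        return float(self.inverse_fn(y))

    # ------------------------------------------------------------------ range

    @property
    def kink(self) -> float:
        """Clamp point of a piecewise-linear shape (cells)."""
        if self.shape != "piecewise_linear":
            raise AttributeError("only piecewise_linear shapes have a kink")
        return (self.saturation - self.intercept) / self.slope

    @property
    def saturation_start(self) -> Optional[float]:
        """x beyond which the function is exactly constant, or None."""
        if self.shape == "piecewise_linear":
            return self.kink
        return None

    @property
    def range(self) -> tuple[float, float]:
        """(inf, sup) of the function over ``[0, inf)``.

        The sup of a sigmoidal shape is an asymptote, not attained; see
        :meth:`attains_sup`.
        """
        if self.shape == "linear":
            if self.slope > 0:
                return self.intercept, math.inf
            if self.slope < 0:
                return -math.inf, self.intercept
            return self.intercept, self.intercept
        if self.shape == "piecewise_linear":
            pair = (self.intercept, self.saturation)
            return (min(pair), max(pair))
        if self.shape == "sigmoidal":
            return self.intercept, self.intercept + self.saturation
        v0 = self.value(0.0)
        v_inf = self.value(_CUSTOM_RANGE_PROBE)
        return (min(v0, v_inf), max(v0, v_inf))

    def attains_sup(self) -> bool:
        return self.shape != "sigmoidal"

    def in_range(self, y: float) -> bool:
        """Whether ``inverse(y)`` is defined."""
        lo, hi = self.range
        if self.shape == "sigmoidal":
            return lo <= y < hi
        return lo <= y <= hi

    # ---------------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        """Flat config mapping (custom shapes cannot be serialised)."""
        if self.shape == "custom":
            raise ValueError("custom feedback functions cannot be serialised")
        out = {"shape": self.shape, "intercept": self.intercept,
               "slope": self.slope, "direction": self.direction}
        for key in ("saturation", "midpoint", "steepness"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "Feedback":
        allowed = {"shape", "intercept", "slope", "saturation",
                   "midpoint", "steepness", "direction"}
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown feedback config keys: {sorted(unknown)}")
        return cls(**mapping)

    def validate_monotone(self, x_max: float = 1e6, n: int = 200) -> None:
        """Check declared monotonicity on a log-spaced grid (raises on failure).

        Intended for ``custom`` shapes whose callables cannot be verified
        symbolically; cheap enough to run on any shape.
        """
        xs = [0.0] + [x_max ** (i / (n - 1)) - 1.0 + 1e-9 for i in range(n)]
        xs = sorted(set(xs))
        vals = [self.value(x) for x in xs]
        sign = 1.0 if self.direction == "increasing" else -1.0
        for (x1, v1), (x2, v2) in zip(zip(xs, vals), zip(xs[1:], vals[1:])):
            if sign * (v2 - v1) < -1e-12 * max(1.0, abs(v1)):
                raise ValueError(
                    f"feedback declared {self.direction} but value({x1:g})={v1:g} "
                    f"-> value({x2:g})={v2:g}")


# ------------------------------------------------------------- constructors

def linear(intercept: float, slope: float) -> Feedback:
    """Unclamped linear feedback ``intercept + slope * x``."""
    direction = "decreasing" if slope < 0 else "increasing"
    return Feedback("linear", intercept=intercept, slope=slope, direction=direction)


def piecewise_linear(intercept: float, slope: float, saturation: float) -> Feedback:
    """Clamped linear feedback; the clamp direction follows the slope sign.

    Increasing (``slope > 0``): ``min(intercept + slope*x, saturation)`` --
    the canonical differentiation-rate shape.  Decreasing (``slope < 0``):
    ``max(intercept + slope*x, saturation)`` -- the dedifferentiation /
    inhibited-growth shape, with ``saturation`` acting as a floor.
    """
    direction = "decreasing" if slope < 0 else "increasing"
    return Feedback("piecewise_linear", intercept=intercept, slope=slope,
                    saturation=saturation, direction=direction)


def sigmoidal(intercept: float, amplitude: float, midpoint: float,
              steepness: float) -> Feedback:
    """Hill-type feedback ``intercept + amplitude * x^p / (midpoint^p + x^p)``."""
    return Feedback("sigmoidal", intercept=intercept, saturation=amplitude,
                    midpoint=midpoint, steepness=steepness)


def custom(value_fn: Callable[[float], float],
           derivative_fn: Optional[Callable[[float], float]] = None,
           inverse_fn: Optional[Callable[[float], float]] = None,
           direction: str = "increasing",
           validate: bool = True) -> Feedback:
    """Wrap user callables as a feedback function.

    ``derivative_fn`` defaults to a central finite difference;
    ``inverse_fn`` is optional (``inverse`` raises without it).  With
    ``validate=True`` monotonicity is sampled on a grid.
    """
    fb = Feedback("custom", direction=direction, value_fn=value_fn,
                  derivative_fn=derivative_fn, inverse_fn=inverse_fn)
    if validate:
        fb.validate_monotone()
    return fb
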