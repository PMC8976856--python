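"""The six one-loop feedback topologies and their screening.

Exactly one of the three rates (beta, delta, omega) is regulated by
exactly one compartment (S or D), giving six wirings.  The two
omega-regulated wirings cannot show homeostasis: with beta and delta both
constant, ``dS/dt = (beta - delta) S`` either never vanishes or vanishes
identically, so S never returns after a perturbation.  The four viable
wirings are

=========  ==========================================  ==============
model id   biology                                     topology
=========  ==========================================  ==============
model 1    D stimulates stem-cell differentiation      ``delta_of_D``
model 2    S stimulates its own differentiation        ``delta_of_S``
model 3    D inhibits stem-cell cycling                ``beta_of_D``
model 4    S inhibits its own cycling                  ``beta_of_S``
=========  ==========================================  ==============

All four share the steady-state relation ``omega = beta * S_bar / D_bar``.
Wherever the stem compartment is regulated solely by D, the steady-state
number of differentiated cells is invariant to the apoptosis rate omega
(write ``alpha(D) = beta(D) - delta(D)``; then ``D_bar = alpha^{-1}(0)``);
the S-regulated analogue holds for ``S_bar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import feedback as fb
from .equilibrium import steady_states, jacobian_at
from .model import ModelSpec, TOPOLOGIES

__all__ = [
    "TopologyTemplate",
    "TopologyReport",
    "enumerate_topologies",
    "viability",
    "eigensystem",
    "analyse_topology",
    "matched_spec",
]

_NON_VIABLE_REASON = ("beta and delta both constant force dS/dt = (beta - "
                      "delta) S; any non-trivial steady state requires beta "
                      "= delta, which makes dS/dt vanish identically -- no "
                      "restoring dynamics after a perturbation of S")

#: model number used in the cross-topology comparisons, by topology id
MODEL_NUMBERS = {"delta_of_D": 1, "delta_of_S": 2, "beta_of_D": 3, "beta_of_S": 4}


@dataclass(frozen=True)
class TopologyTemplate:
    """One wiring of the single feedback loop."""

    topology: str
    regulated_rate: str
    regulator: str
    feedback_direction: str       # increasing (stimulation) or decreasing
    viable: bool
    reason: str = ""


@dataclass
class TopologyReport:
    topology: str
    viable: bool
    steady_state: Optional[tuple[float, float]]
    jacobian: Optional[np.ndarray]
    eigenvalues: Optional[tuple[complex, complex]]
    eigenvectors: Optional[np.ndarray]
    notes: list[str] = field(default_factory=list)


def viability(topology: str) -> tuple[bool, str]:
    """Whether a wiring can sustain homeostasis, with the reason if not."""
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if topology.startswith("omega"):
        return False, _NON_VIABLE_REASON
    return True, ""


def enumerate_topologies() -> list[TopologyTemplate]:
    """All six one-loop wirings ({beta, delta, omega} x {S, D})."""
    out = []
    for topology in TOPOLOGIES:
        rate, reg = topology.split("_of_")
        viable, reason = viability(topology)
        # differentiation is stimulated; cycling (and apoptosis, were it
        # viable) is inhibited by crowding
        direction = "increasing" if rate in ("delta", "omega") else "decreasing"
        out.append(TopologyTemplate(topology=topology, regulated_rate=rate,
                                    regulator=reg, feedback_direction=direction,
                                    viable=viable, reason=reason))
    return out


def eigensystem(spec: ModelSpec) -> tuple[tuple[complex, complex], np.ndarray]:
    """Eigenvalues and eigenvectors of the Jacobian at the non-trivial state.

    Columns of the returned matrix are the eigenvectors, ordered by
    descending real part of their eigenvalues.
    """
    viable, reason = viability(spec.topology)
    if not viable:
        raise ValueError(f"topology {spec.topology} is not viable: {reason}")
    reports = steady_states(spec)
    nontrivial = [r for r in reports if r.kind == "nontrivial"]
    if not nontrivial:
        raise ValueError("no feasible non-trivial steady state for this spec")
    rep = nontrivial[0]
    vals, vecs = np.linalg.eig(rep.jacobian)
    order = np.argsort(-vals.real)
    return ((complex(vals[order[0]]), complex(vals[order[1]])),
            vecs[:, order])


def analyse_topology(spec: ModelSpec) -> TopologyReport:
    """Steady state, Jacobian and eigensystem plus applicable theorems."""
    viable, reason = viability(spec.topology)
    notes: list[str] = []
    if not viable:
        return TopologyReport(spec.topology, False, None, None, None, None,
                              notes=[reason])
    if spec.regulator == "D":
        notes.append("D_bar invariant to omega (stem compartment regulated "
                     "solely by D)")
    else:
        notes.append("S_bar invariant to omega (stem compartment regulated "
                     "solely by S)")
    notes.append("saturating stem-cell rates give a constant S/D ratio "
                 "during unbounded growth")
    reports = steady_states(spec)
    nontrivial = [r for r in reports if r.kind == "nontrivial"]
    if not nontrivial:
        return TopologyReport(spec.topology, True, None, None, None, None,
                              notes=notes + ["no feasible non-trivial steady "
                                             "state for these parameters"])
    rep = nontrivial[0]
    vals, vecs = eigensystem(spec)
    return TopologyReport(spec.topology, True, (rep.S_bar, rep.D_bar),
                          rep.jacobian, vals, vecs, notes=notes)


def matched_spec(topology: str,
                 stem_fraction: float,
                 *,
                 beta: Optional[float] = None,
                 delta0: Optional[float] = None,
                 beta0: Optional[float] = None,
                 delta: Optional[float] = None,
                 total: float = 1100.0) -> ModelSpec:
    """Parameterise a viable topology to a prescribed steady state.

    The steady state is fixed at ``S_bar = stem_fraction * total``,
    ``D_bar = (1 - stem_fraction) * total`` and the feedback slope plus the
    apoptosis rate are solved from the steady-state relations.  This makes
    topologies comparable at matched compositions: delta-regulated models
    take free parameters ``(beta, delta0)`` with ``delta0 < beta``;
    beta-regulated models take ``(beta0, delta)`` with ``delta < beta0``.

    Piecewise-linear feedbacks are used: increasing ones clamp far above
    the steady state (at 10x the regulator's steady value); decreasing
    ones are floored at 0.
    """
    if not 0 < stem_fraction < 1:
        raise ValueError("stem_fraction must be in (0, 1)")
    viable, reason = viability(topology)
    if not viable:
        raise ValueError(f"topology {topology} is not viable: {reason}")
    S_bar = stem_fraction * total
    D_bar = (1.0 - stem_fraction) * total
    rate, reg = topology.split("_of_")
    reg_bar = S_bar if reg == "S" else D_bar
    if rate == "delta":
        if beta is None or delta0 is None:
            raise ValueError("delta-regulated topologies need beta and delta0")
        if not 0 <= delta0 < beta:
            raise ValueError("need 0 <= delta0 < beta for a feasible state")
        slope = (beta - delta0) / reg_bar
        delta_fb = fb.piecewise_linear(delta0, slope,
                                       delta0 + slope * 10.0 * reg_bar)
        omega = beta * S_bar / D_bar
        return ModelSpec(topology=topology, beta=beta, omega=omega,
                         delta=delta_fb)
    if beta0 is None or delta is None:
        raise ValueError("beta-regulated topologies need beta0 and delta")
    if not 0 < delta < beta0:
        raise ValueError("need 0 < delta < beta0 for a feasible state")
    slope = (delta - beta0) / reg_bar
    beta_fb = fb.piecewise_linear(beta0, slope, 0.0)
    omega = delta * S_bar / D_bar
    return ModelSpec(topology=topology, beta=beta_fb, omega=omega, delta=delta)
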