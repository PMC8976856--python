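# Methods

## The model

`cryptdyn` implements a two-compartment population-dynamics model of a
feedback-controlled hierarchical tissue, written for the colon/intestinal
epithelium. Stem cells `S` proliferate with a *realised growth rate* β
(proliferation minus death, before differentiation), differentiate at a
rate δ, and differentiated cells `D` (including transit-amplifying cells)
are lost at an apoptosis rate ω:

    dS/dt = β S − δ(D) S
    dD/dt = δ(D) S − ω D

The differentiation rate is an increasing function of `D`, standing in for
the Ihh/BMP signalling axis by which differentiated cells push stem cells
towards differentiation. This makes the system a substrate-depletion
oscillator: `S` is the substrate, `D` the depleting product.

The extended model adds dedifferentiation, a decreasing function ϱ(S) of
the stem pool, moving cells from `D` back to `S`:

    dS/dt = β S − δ(D) S + ϱ(S) D
    dD/dt = δ(D) S − ϱ(S) D − ω D

### Assumptions

- Well-mixed compartments, deterministic ODEs; no space, no stochasticity,
  no explicit transit-amplifying compartment (folded into `D`).
- δ is continuous, monotone increasing, with a closed-form derivative and
  an inverse on the closure of its strictly monotone branch. The clamp of
  the piecewise-linear shape is a kink: the function is Lipschitz but not
  differentiable there; derivatives at the kink are the left-hand
  derivative and carry an `is_kink` flag. The analysis only ever needs the
  derivative at interior steady states.
- ϱ is continuous, monotone decreasing, non-negative, typically clamped to
  a floor ϱ_min ≥ 0.

## Steady states and stability

The extinct state (0, 0) always exists; it is stable iff β < δ(0). The
interior (homeostatic) state of the basic model is

    D̄ = δ⁻¹(β),   S̄ = ω D̄ / β,

and exists iff the range of δ reaches β. By Routh–Hurwitz it is stable iff
0 < δ′(D̄) < δ(D̄)/D̄. For the piecewise-linear shape
δ(D) = min{δ₀ + δ_slope·D, δ_max} this gives the closed-form spectrum

    λ₁,₂ = (−δ₀ω ± sqrt(−4β³ω + 4β²δ₀ω + δ₀²ω²)) / (2β),

implemented in `eigenvalues_piecewise_linear` and cross-checked in tests
against `numpy.linalg.eigvals` of the analytic Jacobian. Any biologically
feasible interior state (0 < δ₀ < β < δ_max) is stable; the sign of the
radicand separates stable nodes from stable foci. Two structural theorems
are exposed and property-tested: D̄ is invariant to ω whenever the stem
compartment is regulated solely by `D` (and S̄ is invariant to ω in the
S-regulated analogue), and δ₀ = 0 reduces the model to the conservative
predator–prey system with first integral
H = δ_slope·S − ω ln S + δ_slope·D − β ln D.

Regimes are labelled system-wide: `homeostasis` (stable interior state),
`extinction` (β ≤ δ(0), no feasible interior state), `unbounded_growth`
(no interior state, unstable extinct state) and `sustained_oscillation`
(interior state unstable with a complex pair, e.g. a sigmoidal feedback
steeper than p* = 4β/δ_max when the steady state sits at the Hill
midpoint). "Sustained" is asserted numerically (non-decaying amplitude
over 20 periods), not proven as a limit cycle.

### A note on the angular frequency

For the damped oscillations of the piecewise-linear model the canonical
angular frequency is |Im λ| of the spectrum above. A closed-form frequency
expression in circulation for this model,
sqrt(δ_slope·D̄·(4β²ω + ω²) − βω²)/(2β), does **not** reduce to |Im λ|
under the steady-state substitution δ₀ = β − δ_slope·D̄ (at the standard
parametrisation: 0.0881 vs 0.0893). `oscillation_metrics` reports both,
with `alt_consistent=False`; the package deliberately does not reconcile
them.

## Escape growth

When β exceeds the saturation value δ_max the feedback can no longer
balance proliferation and the saturated dynamics are linear. The exact
solution is

    S(t) = S₀ e^{bt},   D(t) = (D₀ − A) e^{−ωt} + A e^{bt},
    b = β − δ_max,      A = S₀ δ_max / (b + ω).

A commonly quoted form of D(t) drops the decaying correction −A·e^{−ωt}
(the lower-limit term of the convolution integral) and violates
D(0) = D₀; the asymptotics are unaffected. The stem-to-differentiated
ratio converges to (β + ω)/δ_max − 1, the total population grows at rate
b with prefactor (β+ω)/(β+ω−δ_max), and with dedifferentiation floored at
ϱ_min the ratio generalises to (a + b + w)/(2δ_max), a = sqrt(4δ_max ϱ_min
+ (b+w)²), w = ω + ϱ_min — reducing exactly to the basic ratio at
ϱ_min = 0. Simulated ratios from the full nonlinear system start the
comparison only after both feedbacks are saturated; "large t" is
operationalised as ≳ 20/(β − δ_max), separating the growing and decaying
modes by 20 e-folds. Unbounded-growth runs cap `t_end` and estimate the
rate by a log-linear fit on the trajectory tail rather than integrating
towards overflow.

## Topology family

Exactly one of {β, δ, ω} regulated by exactly one of {S, D} gives six
one-loop wirings. The ω-regulated pair cannot show homeostasis (with β
and δ constant, dS/dt = (β−δ)S has no isolated interior zero). The four
viable wirings share ω = β·S̄/D̄ at steady state, and their Jacobians,
expressed through (β, δ₀, ω) — or (β₀, δ, ω) for inhibited cycling — do
not contain the feedback slope: at fixed rates the slope only rescales
the steady state, leaving the dynamics per unit displacement invariant.
For cross-model comparisons `matched_spec` pins the steady state at
(S̄, D̄) = (sf·N, (1−sf)·N) with N = 1100 cells and stem fractions
sf ∈ {1%, 10%, 25%}, solving slope and ω per topology.

## The defect statistic

Recovery quality after removing a fraction f of `D`, `S`, or both is the
defect

    χ = ∫₀^∞ (D̄ − D(t)) · 1[D(t) < D̄] dt,

the cumulative shortfall of differentiated cells (only sub-steady
intervals count — that is when tissue function is lacking). Two routes:

- **numerical**: integrate with dense output to a truncation horizon
  where the linear envelope falls below 1e-6·D̄ (plus one period of
  margin, ×1.25 for nonlinear transients); locate crossings of D = D̄ by
  sign scan + Brent refinement; `scipy.integrate.quad` on each sub-steady
  interval.
- **linearised**: write the relaxation in the steady-state Jacobian's
  eigenbasis. Focus: ΔD(t) = R e^{at} cos(wt − ψ), defect summed
  half-period by half-period with the analytic antiderivative until the
  envelope truncation criterion. Node: two-exponential deviation with at
  most one sign change, integrated in closed form to infinity. A
  defective Jacobian falls back to the numerical route with a warning.

In the linear regime χ is proportional to the initial displacement, so
comparisons are reported per unit displacement (ΔD(0), or ΔS(0) for pure
stem-cell removal). The two routes agree to ≤1.6% at f = 0.1 for
removal of differentiated cells across the random stable ensemble. For
stem-cell removal the relaxation leaves the linear regime sooner: the
discrepancy is ~4% at f = 0.1 and scales linearly in f (0.4% at
f = 0.01); this is a property of the dynamics, not of either algorithm,
and is pinned by a dedicated test.

Comparison maps between the two δ-regulated wirings share parameters
(β, δ₀) and are evaluated pointwise on grids β ∈ [0.5, 2],
δ₀/β ∈ [0.5, 0.999] (chosen as plausible defaults; configurable). Models
with different parameter spaces (β₀, δ) are compared by defect ranges
only. The qualitative structure reproduced by the tests: the crypt wiring
recovers worse from stem-cell removal at small stem fractions, better
from differentiated-cell removal whenever δ₀ ≈ β, indirect cycling
inhibition lands in overlapping ranges, and self-inhibited cycling with a
small differentiation rate is slower by orders of magnitude.

## Dedifferentiation and recovery

With ϱ(S) = max{ϱ₀ + ϱ_slope·S, ϱ_min}, the interior state solves
β − δ((β/ω)S̄) + (β/ω)ϱ(S̄) = 0 (bracketed scalar root finding on a
2000-point grid past both saturation points; all sign-change roots are
reported, tangency double roots may be missed). A strong enough ϱ
destroys the root — a second route out of homeostasis.

In the Fig-4b-style scenarios ϱ is clamped so that ϱ(S̄) = 0: the steady
state of the basic model is preserved and dedifferentiation acts only
during deep transients (the scenario removes 90% of stem cells, chosen so
that the trajectory actually enters the ϱ > 0 region; the fraction is a
package choice). Adding ϱ always accelerates the decay of oscillations.
The basal-rate threshold

    ϱ₀* = (β − δ₀/2) · 4ω²/β²

separates frequency increase from frequency reduction relative to ϱ ≡ 0.
It acts through the local spectrum only when ϱ is non-zero near the
steady state, so the package verifies it in the near-constant-ρ limit
(ϱ_slope = −1e-6): with ρ ≈ ϱ₀ near the (shifted) steady state one gets
Δω₀²(ϱ₀) = ϱ₀[β − δ₀/2 − ϱ₀β²/(4ω²)], which is positive exactly for
0 < ϱ₀ < ϱ₀* — the implementation checks this by eigenvalues and by
zero-crossing measurements on simulations.

## Numerical choices

- Integrator: `solve_ivp` RK45, rtol 1e-8, atol 1e-10, dense output;
  `Radau` selectable. Kinks of clamped feedbacks need no event handling
  (measure-zero, RHS Lipschitz). Trajectory values below −10·atol trigger
  a warning and are clipped to 0 (the model is positively invariant
  analytically).
- Marginality: |Re λ| < 1e-9 · max rate scale classifies as `marginal`,
  guarding sign tests at stability boundaries. At β = δ_max the
  piecewise-linear interior state still exists (the clamp attains δ_max):
  regimes flip strictly above. At δ₀ = β the interior state degenerates
  to (0, 0) and the regime is labelled extinction.
- Zero-crossing frequency measurement discards half-periods whose
  amplitude falls below a floor (default 1% of the peak deviation) —
  below it, crossings are solver noise.
- Defect truncation times are recorded in every `DefectResult`.

## Scenario generator and what it does (not) show

`random_stable_specs` draws crypt-model parameters with β ∈ [0.5, 2],
δ₀/β ∈ [0.5, 0.999], ω log-uniform in [0.05, 0.5] (kept away from very
small ω so defect horizons stay bounded), δ_slope log-uniform in
[1e-5, 1e-3], δ_max ∈ [1.5, 3]·β — the same plausible ranges as the
comparison grids. Every draw is verified stable by the classifier.
Presets pin the canonical worked examples (standard parametrisation,
escape scenario, slope family with the steady state re-solved via
δ₀ = β − δ_slope·D̄, dedifferentiation columns).

These synthetic conditions exercise the mathematics of the model family;
they do not emulate any experimental dataset (none exists for this
model), so passing tests certify the analysis machinery, not biological
calibration. Known limitations: no multi-loop topologies, no Hopf
normal-form or limit-cycle continuation, no stochastic variants, and the
linearised defect inherits the ~O(f) linearisation error described above.
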