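# Methods

## The model

The built-in network encodes cellular cholesterol regulation as 22
biochemical processes over 14 species: the SREBP/Scap/Insig sensing complex
(`Sci`) and the three SREBP transcription factors it releases (`Sr`, `Sh`,
`Sp`); the proteins they induce — LDL receptor `R`, HMG-CoA reductase `HR`,
PCSK9 `P`; the metabolic intermediates HMG-CoA `H` and LDL-derived free
cholesterol `Cf`; the cholesterol pools of the plasma membrane (`Cp`), ER
membrane (`Ce`) and ester reservoir (`E`); lumenal "active" cholesterol `C`;
and the extracellular lipoprotein input `CL`. The PCSK9-mediated receptor
degradation chain `P + R → P → ∅` contributes two irreversible reactions,
so the reaction list has 23 entries carrying the 23 rate constants
(`k1…k16`, `p1…p3`, `μ`, `η`, `α`, `θ`).

Modelling conventions:

- **Chemostatted input.** `CL` is a true species of the graph (it appears
  in the complexes `R + CL` and `R + Cf` via the uptake reaction) but is
  held constant in the dynamics, leaving 13 rate equations. This single
  convention reproduces both the graph analysis and the ODE system.
- **Reversible arrows** are stored as two irreversible reactions; the file
  dialect's `<->` is sugar only.
- **The zero complex** is written `0` in files and rendered `∅` in reports.
- Rate values live in `ParameterSet`, not in the network: one network, many
  parameterizations.
- Retention of the sensing complex is modelled as net removal
  `Sci + C → ∅`; the retained complex is not tracked as an explicit inert
  species (it never re-enters the dynamics).

## Graph invariants

Complexes are canonicalized as name-sorted multisets, so `Ce + HR` and
`HR + Ce` are one vertex. Linkage classes are weakly connected components
of the complex multigraph, strong linkage classes its strongly connected
components; a strong class is terminal when no reaction leaves it. The
stoichiometric rank is computed in exact rational arithmetic (sympy over
the integer stoichiometry matrix): the deficiency δ = m − l − s is an
integer invariant and floating-point rank would be unacceptable.

For the full network the exact computation gives m = 23, l = 2, s = 14 and
δ = 7. Note that s can never exceed the species count (14 here); the
pipeline report carries an explicit note to that effect. The decomposition
shipped with the package assigns the eight reactions
{∅→Sci; Sci+C→∅; Ce→Ce+C; Cf→Cp; Cp⇌Ce; Ce⇌E} to subnetwork 1
(m=8, l=2, s=5, δ=1) and the remaining 15 to subnetwork 2 (s=9); the ranks
are additive (5 + 9 = 14), so the two subnetworks are algebraically
independent and their steady states decouple. Subnetwork 1 refines further
into 1A (the antithetic sequestration cycle, δ=1) and 1B (the passive
cholesterol fluxes, δ=0), again rank-additive (2 + 3 = 5). Within
subnetwork 1 the non-terminal complexes are ∅, Sci+C, Ce, Cp, Cf and E;
note that it is the *pair* complex `Sci + C` (not the singleton `Sci`) that
is non-terminal under this reconstruction.

The Shinar–Feinberg screen applies only at deficiency exactly one. "Differ
in a single species" is implemented as: the multiset difference of the two
non-terminal complexes has support of size one, any multiplicity — e.g.
(∅, Ce) differ only in `Ce`. Non-terminal status is always evaluated within
the subnetwork under analysis, not inherited from the parent network, which
is what the theorem requires.

## Steady-state algebra

Parameters (rate constants) are elements of the coefficient field, never
ring variables; the polynomial ring is in the 13 dynamic species and the
input. Elimination proceeds in two stages:

1. **Exact sequential substitution.** Any generator linear in an eliminated
   variable whose leading coefficient is parameter-only can be solved by a
   unit of the coefficient field; substituting it out changes neither the
   ideal nor its elimination. This resolves most of the triangular
   structure cheaply.
2. **Block-order Gröbner basis** over `QQ(parameters)` with a lex order
   placing eliminated variables first, for whatever remains.

Results are normalized to content-free form with a positive leading
coefficient in the kept species (hence "`⟨θCe − μ⟩` up to unit") and, on
request, cross-checked by Gröbner elimination over the rationals after
random rational parameter substitution (five seeds in the test suite; a
mismatch raises).

`classify_rpa` accepts a polynomial exactly when it has a linear factor in
the candidate species whose root is free of every species and input symbol.
When several factors qualify, a provably positive root is preferred (rate
symbols carry positivity assumptions): setpoints are concentrations. In the
whole-network screen a zero setpoint is not counted as adaptation — a
species driven to extinction is not homeostatic.

The lift is found by a linear ansatz: constant coefficients first, then
polynomial coefficients of increasing total degree (default cap 1). The
controller is identified by the RPA polynomial admitting a
*constant-coefficient* lift; that combination is the time derivative of the
integral variable Σ rᵢ·xᵢ (here `C − Sci`, with `d(C−Sci)/dt = θCe − μ`).
Uniqueness of the certificate is claimed only modulo the linear-syzygy
module: since a linear syzygy of mass-action rate equations is exactly a
constant left-null vector of the dynamic stoichiometric matrix, the empty
null space (checked both ways) makes the constant certificate unique.

Closed-form steady states are obtained by the same successive-linear-solve
idea applied to all variables; the solver raises when no equation is linear
in a single remaining unknown, directing callers to numeric root finding.
Each closed form is returned with strict-positivity conditions (numerator ×
denominator > 0) used by the sweep's feasibility classification. The unique
triangular solution branch is assumed throughout; no other steady-state
branches exist for this system.

## Dynamics and verification

Simulations use `scipy.solve_ivp` (LSODA by default) with relative
tolerance 1e−8 and absolute tolerance 1e−10, restarting at every input
switch. The demonstration protocol steps the input through levels
(1, 2, 4). Segment length matters for *verification*: the slowest Jacobian
eigenvalue at the reference parameters is ≈ −0.029 at CL = 4, so
convergence-critical checks use 1500 time units per segment, while the
quick-look default is 100. `verify_rpa` refuses to give a verdict
("inconclusive") unless the end-of-segment right-hand-side residual norm is
below 1e−8 (relative to the state magnitude) — a fixed horizon would be
wrong for parameter-dependent time scales. A species passes when its
end-of-segment values match the declared setpoint to 1e−5 relative
tolerance at every input level.

## Stability sweep

Each draw assigns all 23 rate constants — and, by default, the input level —
i.i.d. uniform values on the *open* interval (1, 50) (endpoint draws are
rejected, a probability-zero event). The input is sampled because it enters
the Jacobian and the steady state exactly like a rate constant does in this
analysis; a flag fixes it instead. Draws are deterministic given the seed,
with per-trial seeding via `SeedSequence([seed, trial])`.

For each draw the closed-form steady state is evaluated, the Jacobian is
evaluated there, and the draw is classified stable when max Re λ < −1e−9
(the margin avoids floating-point boundary flips). Because a random draw
need not admit a positive steady state (feasibility requires, e.g.,
`k12·μ > θ·α`), three documented modes are reported:

- `formal` (default): classify by the eigenvalues at the algebraic steady
  state regardless of its sign — what a symbolic solve-then-eigenvalue
  pipeline computes when no positivity screen is applied;
- `strict`: non-positive steady states count as not stable;
- `feasible_only`: they are excluded from the denominator.

At 10,000 draws × 10 trials the formal and strict modes give ≈ 41% stable
per trial (empirically they coincide: draws with a non-positive steady
state are never formally stable in this system), with per-trial spread
under 2 percentage points; among feasible draws ≈ 97% are stable. The
agreement between linear stability and nonlinear relaxation is checked by
simulation from a 5% perturbation of the steady state on 100 feasible
draws; draws with |max Re λ| < 1e−3 are skipped as numerically marginal.

## Synthetic inputs

The random-CRN generator exists to exercise the graph and algebra machinery
against brute-force oracles: it draws small complexes (size ≤ 2 by default,
mirroring the bimolecular structure of the fixture), rejects duplicate
reactions and reactant-equals-product loops, and is deterministic by seed.
The generated corpus deliberately covers multiple linkage classes,
non-trivial strong components and conservation laws. It does not attempt
biologically calibrated kinetics, and the parameter sampler is a plain
uniform design — no Latin-hypercube or Sobol variants.

What passing tests show, and what they do not: the synthetic corpus
validates the *combinatorial and algebraic* machinery exactly, and the
reference parameterization validates the dynamics against closed forms; no
claim is made that uniform (1, 50) kinetics resemble measured cholesterol
kinetics, nor that the 22-process network captures oxysterol signalling,
LXR/Idol transcription detail or receptor recycling, all of which are
outside this model's scope.

## Problem sizes

The shipped test suite runs the full 10,000 × 10 sweep (seconds on one
core), 1,000 random networks for the graph property suite, 100 draws for
the eigenvalue-versus-simulation agreement check, and five random-rational
substitutions per elimination verification.

## Known limitations

- The closed-form solver and the fast elimination path assume the
  quasi-triangular structure typical of these networks; fully coupled
  nonlinear steady states fall back to (slower) Gröbner computation or
  numeric root finding.
- Lift certificates are searched up to a configurable coefficient degree
  (default 1); ideal members requiring higher-degree certificates raise.
- The sweep classifies local (linear) stability only; no bifurcation or
  basin analysis.
- Stochastic (discrete-count) semantics, SBML import/export and units
  checking are out of scope.
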