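"""Symbolic mass-action kinetics: ODE generation, steady states, Jacobian.

Under mass-action kinetics each reaction proceeds at its rate constant
times the product of reactant concentrations raised to their
multiplicities.  For each non-chemostatted species ``X`` the right-hand
side is::

    dX/dt = sum over reactions of  net_stoich(X) * k * prod(reactant^mult)

Chemostatted species (the lipoprotein input ``CL`` in the cholesterol
network) appear as plain symbols inside the monomials but carry no
equation, so the cholesterol network yields a 13-equation polynomial
system.

The steady-state solver exploits the triangular structure typical of such
networks: it repeatedly finds an equation linear in a single remaining
unknown, solves it exactly, and substitutes.  The result is a closed-form
steady state in the rate constants and the input level, together with the
positivity conditions under which it is a genuine (feasible) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

from .crn import CRN, ParameterSet

__all__ = [
    "OdeSystem",
    "SteadyState",
    "NotTriangularizableError",
    "build_ode_system",
    "closed_form_steady_state",
    "jacobian",
]


class NotTriangularizableError(Exception):
    """The steady-state system could not be solved by successive linear steps.

    Callers should fall back to numeric root finding on the right-hand
    sides in this case.
    """


@dataclass(frozen=True)
class OdeSystem:
    """Polynomial mass-action ODE system for the dynamic species of a CRN."""

    crn: CRN
    variables: tuple[sp.Symbol, ...]
    inputs: tuple[sp.Symbol, ...]
    parameters: tuple[sp.Symbol, ...]
    rhs: tuple[sp.Expr, ...]

    @property
    def rhs_map(self) -> dict[sp.Symbol, sp.Expr]:
        return dict(zip(self.variables, self.rhs))

    def symbol(self, name: str) -> sp.Symbol:
        for s in (*self.variables, *self.inputs, *self.parameters):
            if s.name == name:
                return s
        raise KeyError(name)

    def substitutions(self, params: ParameterSet) -> dict[sp.Symbol, float]:
        subs = {p: params[p.name] for p in self.parameters}
        for u in self.inputs:
            subs[u] = params.input_level
        return subs


def build_ode_system(crn: CRN) -> OdeSystem:
    """Generate the symbolic mass-action rate equations of a CRN."""
    species_syms = {s: sp.Symbol(s, positive=True) for s in crn.species}
    param_syms = {r: sp.Symbol(r, positive=True) for r in crn.rate_symbols}
    variables = tuple(species_syms[s] for s in crn.dynamic_species)
    inputs = tuple(species_syms[s] for s in crn.species if s in crn.chemostatted)
    rhs = []
    for s in crn.dynamic_species:
        expr = sp.Integer(0)
        for rx in crn.reactions:
            net = rx.net_stoichiometry(s)
            if net == 0:
                continue
            monomial = param_syms[rx.rate_symbol]
            for name, mult in rx.reactant.terms:
                monomial *= species_syms[name] ** mult
            expr += net * monomial
        rhs.append(sp.expand(expr))
    return OdeSystem(
        crn=crn,
        variables=variables,
        inputs=inputs,
        parameters=tuple(param_syms[r] for r in crn.rate_symbols),
        rhs=tuple(rhs),
    )


@dataclass(frozen=True)
class SteadyState:
    """Closed-form steady state: one expression per dynamic species.

    Expressions involve only rate constants and input symbols.  The
    ``conditions`` are the strict-positivity predicates under which the
    steady state is feasible (every concentration positive and every
    intermediate denominator nonzero).
    """

    solutions: Mapping[sp.Symbol, sp.Expr]
    conditions: tuple[sp.Expr, ...] = ()

    def __getitem__(self, var: sp.Symbol) -> sp.Expr:
        return self.solutions[var]

    def by_name(self) -> dict[str, sp.Expr]:
        return {v.name: e for v, e in self.solutions.items()}

    def evaluate(self, odes: OdeSystem, params: ParameterSet) -> dict[str, float]:
        subs = odes.substitutions(params)
        return {
            v.name: float(e.subs(subs)) for v, e in self.solutions.items()
        }

    def residuals(self, odes: OdeSystem) -> list[sp.Expr]:
        """Symbolic residuals of the rate equations at the steady state (all zero)."""
        return [
            sp.simplify(sp.together(f.subs(self.solutions))) for f in odes.rhs
        ]


def closed_form_steady_state(odes: OdeSystem) -> SteadyState:
    """Solve the steady-state system by successive linear elimination.

    At each step an equation that is linear in one still-unknown variable
    (after substituting the partial solution and clearing denominators) is
    solved exactly.  Raises :class:`NotTriangularizableError` when no such
    step exists, which directs the caller to numeric root finding.
    """
    eqs: list[sp.Expr] = list(odes.rhs)
    unsolved = list(odes.variables)
    solved: list[tuple[sp.Symbol, sp.Expr]] = []
    conditions: list[sp.Expr] = []

    while unsolved and eqs:
        progress = False
        for var in list(unsolved):
            hit = None
            for i, eq in enumerate(eqs):
                if var not in eq.free_symbols:
                    continue
                poly = sp.Poly(sp.numer(sp.together(eq)), var)
                if poly.degree() == 1:
                    hit = (i, poly)
                    break
            if hit is None:
                continue
            i, poly = hit
            c1, c0 = poly.nth(1), poly.nth(0)
            sol = sp.cancel(-c0 / c1)
            solved.append((var, sol))
            unsolved.remove(var)
            del eqs[i]
            eqs = [
                e if var not in e.free_symbols
                else sp.numer(sp.together(e.subs(var, sol)))
                for e in eqs
            ]
            eqs = [e for e in eqs if sp.simplify(e) != 0]
            progress = True
            break
        if not progress:
            raise NotTriangularizableError(
                f"no equation linear in a single unknown among {unsolved}; "
                "use numeric root finding on the right-hand sides"
            )
    if unsolved:
        raise NotTriangularizableError(f"unsolved variables remain: {unsolved}")

    # Back-substitute so every solution involves only parameters and inputs.
    resolved: dict[sp.Symbol, sp.Expr] = {}
    for var, expr in reversed(solved):
        resolved[var] = sp.cancel(expr.subs(resolved))
    solutions = {v: resolved[v] for v in odes.variables}
    for v in odes.variables:
        num, den = sp.fraction(sp.together(solutions[v]))
        conditions.append(sp.Gt(num * den, 0))
    return SteadyState(solutions=solutions, conditions=tuple(conditions))


def jacobian(
    odes: OdeSystem,
    at: SteadyState | Mapping[sp.Symbol, sp.Expr] | None = None,
) -> sp.Matrix:
    """Jacobian of the right-hand sides with respect to the dynamic variables.

    Input symbols are not Jacobian columns.  If ``at`` is given (a steady
    state or any symbol-to-value mapping) the matrix is evaluated there.
    """
    mat = sp.Matrix(odes.rhs).jacobian(odes.variables)
    if at is None:
        return mat
    subs = at.solutions if isinstance(at, SteadyState) else at
    return mat.subs(subs)
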