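"""Steady-state ideal algebra: elimination, RPA polynomials, lift, syzygies.

A network has the capacity for robust perfect adaptation (RPA) in a species
``xi`` when its steady-state ideal contains an *RPA polynomial*

    rho = g(xi, xj) * (xi - c)

whose setpoint ``c`` involves only rate constants — no species and no input.
The two-variable elimination ideal ``<f1,...,fn> ∩ R[xi, input]`` makes this
test effective: throughout, the rate constants live in the coefficient
field, so "parameter-only" means "free of every species and input symbol".

The elimination routine uses a structured fast path — sequential
substitution of variables from equations that are linear in them, which
fully resolves triangularizable mass-action systems — and falls back to a
lex-order Groebner basis for any residual system.  Results are
cross-checked by Groebner elimination over the rationals after random
rational parameter substitution.

The *lift* of an ideal member expresses it as a combination of the
generators; a constant-coefficient lift identifies the linear coordinate
change (the integral variable of the underlying controller, here the
antithetic difference ``C - Sci``).  Linear syzygies — constant vectors
annihilating the rate equations — are exactly the mass conservation laws,
computed from the left null space of the dynamic stoichiometric matrix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import sympy as sp

from .crn import CRN, stoichiometry_matrix
from .mass_action import OdeSystem, build_ode_system

__all__ = [
    "RpaPolynomial",
    "LiftCertificate",
    "SyzygyReport",
    "RpaReport",
    "IdealMembershipError",
    "EliminationError",
    "steady_state_ideal",
    "elimination_ideal",
    "classify_rpa",
    "lift_combination",
    "integral_variable",
    "linear_syzygies",
    "rpa_report",
]


class EliminationError(Exception):
    """Elimination failed or its verification did not agree."""


class IdealMembershipError(Exception):
    """The target polynomial is not recognised as an ideal member."""


def steady_state_ideal(odes: OdeSystem) -> list[sp.Expr]:
    """Generators of the steady-state ideal: the rate polynomials, in order."""
    return [sp.expand(f) for f in odes.rhs]


def _normalize(expr: sp.Expr, keep: Sequence[sp.Symbol]) -> sp.Expr:
    """Content-free form with positive leading coefficient in the kept symbols."""
    poly = sp.Poly(sp.expand(expr), *keep)
    _, prim = sp.Poly(poly, *keep).primitive()
    lead = prim.LC()
    if lead.could_extract_minus_sign():
        prim = -prim
    return prim.as_expr()


def elimination_ideal(
    generators: Sequence[sp.Expr],
    variables: Sequence[sp.Symbol],
    keep: Sequence[sp.Symbol],
    verify_seeds: int = 0,
) -> list[sp.Expr]:
    """Generators of ``<generators> ∩ R[keep]`` with parameters in the coefficients.

    ``variables`` are the ring variables (species and inputs); every other
    symbol is treated as a coefficient-field parameter.  ``verify_seeds``
    > 0 additionally cross-checks the result against a Groebner-basis
    elimination over the rationals under that many random rational
    parameter substitutions, raising :class:`EliminationError` on mismatch.
    """
    keep = list(keep)
    eliminate = [v for v in variables if v not in keep]
    params = sorted(
        {s for g in generators for s in g.free_symbols} - set(variables),
        key=lambda s: s.name,
    )
    eqs = [sp.expand(g) for g in generators]
    eqs = [e for e in eqs if e != 0]

    # Exact sequential substitution: a pivot equation linear in an eliminated
    # variable whose leading coefficient is parameter-only is solvable by a
    # unit of the coefficient field, so eliminating through it changes
    # neither the ideal nor its elimination.
    progress = True
    while progress:
        progress = False
        for var in eliminate:
            for i, eq in enumerate(eqs):
                if var not in eq.free_symbols:
                    continue
                poly = sp.Poly(eq, var)
                if poly.degree() != 1:
                    continue
                c1 = poly.nth(1)
                if set(c1.free_symbols) & set(variables):
                    continue
                c0 = poly.nth(0)
                eqs.pop(i)
                eqs = [
                    e if var not in e.free_symbols
                    else sp.expand(sp.numer(sp.together(e.subs(var, -c0 / c1))))
                    for e in eqs
                ]
                eqs = [e for e in eqs if e != 0]
                progress = True
                break
            if progress:
                break

    if any(set(e.free_symbols) & set(eliminate) for e in eqs):
        # residual system: block elimination via a lex Groebner basis with
        # the rate constants in the coefficient field
        domain = sp.QQ.frac_field(*params) if params else sp.QQ
        gb = sp.groebner(eqs, *eliminate, *keep, order="lex", domain=domain)
        done = [
            sp.numer(sp.together(g))
            for g in gb.exprs
            if not (set(g.free_symbols) & set(eliminate))
        ]
    else:
        done = eqs

    result: list[sp.Expr] = []
    for g in done:
        if g == 0:
            continue
        norm = _normalize(g, keep)
        if norm not in result:
            result.append(norm)
    # discard generators that are multiples of a simpler one
    reduced: list[sp.Expr] = []
    for g in sorted(result, key=sp.count_ops):
        if not any(sp.simplify(sp.div(g, h, *keep)[1]) == 0 for h in reduced):
            reduced.append(g)

    if verify_seeds:
        _verify_elimination(generators, variables, keep, reduced, verify_seeds)
    return reduced


def _verify_elimination(
    generators: Sequence[sp.Expr],
    variables: Sequence[sp.Symbol],
    keep: Sequence[sp.Symbol],
    result: Sequence[sp.Expr],
    n_seeds: int,
) -> None:
    """Check agreement with rational Groebner elimination under random parameters."""
    params = sorted(
        {s for g in generators for s in g.free_symbols} - set(variables),
        key=lambda s: s.name,
    )
    eliminate = [v for v in variables if v not in keep]
    for seed in range(n_seeds):
        rng = random.Random(seed)
        subs = {
            p: sp.Rational(rng.randint(1, 400), rng.randint(1, 9)) for p in params
        }
        gb = sp.groebner(
            [g.subs(subs) for g in generators], *eliminate, *keep, order="lex"
        )
        oracle = [
            g for g in gb.exprs if not (set(g.free_symbols) & set(eliminate))
        ]
        ours = [sp.expand(g.subs(subs)) for g in result]
        ours = [g for g in ours if g != 0]

        def monic_basis(polys: list[sp.Expr]) -> set[sp.Expr]:
            if not polys:
                return set()
            basis = sp.groebner(polys, *keep, order="lex").exprs
            return {sp.expand(sp.monic(sp.Poly(b, *keep)).as_expr()) for b in basis}

        if monic_basis(oracle) != monic_basis(ours):
            raise EliminationError(
                f"elimination ideal mismatch under substitution seed {seed}"
            )


@dataclass(frozen=True)
class RpaPolynomial:
    """A factored RPA polynomial ``rho = g * (xi - c)`` with parameter-only setpoint."""

    rho: sp.Expr
    factor_g: sp.Expr
    rpa_variable: sp.Symbol
    free_variable: sp.Symbol
    setpoint: sp.Expr

    def verify(self) -> bool:
        return (
            sp.expand(
                self.rho - self.factor_g * (self.rpa_variable - self.setpoint)
            )
            == 0
        )


def classify_rpa(
    poly: sp.Expr,
    xi: sp.Symbol,
    xj: sp.Symbol,
    forbidden: Sequence[sp.Symbol] = (),
) -> RpaPolynomial | None:
    """Accept ``poly`` iff it factors as ``g(xi,xj) * (xi - c)`` with parameter-only ``c``.

    ``forbidden`` lists additional symbols (other species) that must not
    appear in the setpoint; ``xi`` and ``xj`` are always excluded.
    Rejection is signalled by ``None``.
    """
    banned = set(forbidden) | {xi, xj}
    expr = sp.expand(poly)
    if expr == 0 or xi not in expr.free_symbols:
        return None
    candidates: list[RpaPolynomial] = []
    _, factors = sp.factor_list(expr, xi, xj)
    for base, _mult in factors:
        p = sp.Poly(base, xi)
        if p.degree() != 1:
            continue
        c1, c0 = p.nth(1), p.nth(0)
        if set(c1.free_symbols) & banned or set(c0.free_symbols) & banned:
            continue
        setpoint = sp.cancel(-c0 / c1)
        g, rem = sp.div(expr, xi - setpoint, xi)
        if sp.simplify(rem) != 0:
            continue
        candidates.append(
            RpaPolynomial(
                rho=expr,
                factor_g=sp.expand(g),
                rpa_variable=xi,
                free_variable=xj,
                setpoint=setpoint,
            )
        )
    if not candidates:
        return None
    # a setpoint is a concentration: prefer a provably positive root (the
    # rate symbols carry positivity assumptions), then any nonzero one
    for cand in candidates:
        if cand.setpoint.is_positive:
            return cand
    for cand in candidates:
        if cand.setpoint != 0:
            return cand
    return candidates[0]


@dataclass(frozen=True)
class LiftCertificate:
    """Coefficients ``r1..rn`` with ``sum(ri * fi) == target``."""

    coefficients: tuple[sp.Expr, ...]
    target: sp.Expr
    unique: bool = False

    @property
    def is_constant(self) -> bool:
        return all(c.is_number for c in self.coefficients)

    def verify(self, generators: Sequence[sp.Expr]) -> bool:
        acc = sum(c * g for c, g in zip(self.coefficients, generators))
        return sp.expand(acc - self.target) == 0


def lift_combination(
    generators: Sequence[sp.Expr],
    target: sp.Expr,
    variables: Sequence[sp.Symbol],
    max_degree: int = 1,
    syzygies: "SyzygyReport | None" = None,
) -> LiftCertificate:
    """Express ``target`` as a combination of the generators.

    Tries a constant-coefficient combination first, then polynomial
    coefficients of increasing total degree in ``variables`` (coefficients
    may involve parameters linearly through the unknowns they multiply).
    Raises :class:`IdealMembershipError` when no combination up to
    ``max_degree`` exists.  The certificate is flagged unique when it is
    constant and the syzygy report (computed if not supplied) is empty.
    """
    target = sp.expand(target)
    if target == 0:
        cert = tuple(sp.Integer(0) for _ in generators)
        return LiftCertificate(cert, target, unique=False)
    monoms = [sp.Integer(1)]
    for degree in range(0, max_degree + 1):
        if degree > 0:
            monoms = list(
                sp.itermonomials(list(variables), degree, degree)
            ) + monoms
        unknowns = []
        combo = sp.Integer(0)
        for i, g in enumerate(generators):
            for j, m in enumerate(monoms):
                u = sp.Symbol(f"_r_{i}_{j}")
                unknowns.append(u)
                combo += u * m * g
        residual = sp.expand(combo - target)
        poly = sp.Poly(residual, *variables)
        eqs = list(poly.coeffs())
        # each coefficient is linear in the unknowns with parameter coefficients;
        # match parameter monomials as well
        lin_eqs = []
        params = sorted(
            (set(residual.free_symbols) - set(variables) - set(unknowns)),
            key=lambda s: s.name,
        )
        for e in eqs:
            p = sp.Poly(e, *params) if params else None
            lin_eqs.extend(p.coeffs() if p is not None else [e])
        sol = sp.linsolve(lin_eqs, unknowns)
        if sol and sol != sp.EmptySet:
            # free unknowns appear as themselves in the parametric solution;
            # pick the particular solution with all of them zero
            zero_free = {u: 0 for u in unknowns}
            vec = [sp.expand(v.subs(zero_free)) for v in list(sol)[0]]
            coeffs = []
            k = 0
            for i, _g in enumerate(generators):
                acc = sp.Integer(0)
                for m in monoms:
                    acc += vec[k] * m
                    k += 1
                coeffs.append(sp.expand(acc))
            cert = LiftCertificate(tuple(coeffs), target)
            if not cert.verify(generators):
                continue
            if cert.is_constant:
                syz = syzygies or linear_syzygies(generators, variables)
                cert = LiftCertificate(
                    cert.coefficients, target, unique=not syz.linear_syzygies
                )
            return cert
    raise IdealMembershipError(
        f"no polynomial combination of degree <= {max_degree} yields the target"
    )


def integral_variable(
    cert: LiftCertificate, variables: Sequence[sp.Symbol]
) -> sp.Expr:
    """The linear coordinate ``sum(ri * species_i)`` of a constant certificate.

    For the antithetic controller of the cholesterol network this is the
    sequestration difference ``C - Sci``, whose time derivative equals the
    regulation error ``theta*Ce - mu``.
    """
    if not cert.is_constant:
        raise ValueError(
            "certificate has non-constant coefficients; not a linear coordinate change"
        )
    return sp.expand(
        sum(c * v for c, v in zip(cert.coefficients, variables))
    )


@dataclass(frozen=True)
class SyzygyReport:
    """Basis of constant-coefficient vectors annihilating the generators."""

    linear_syzygies: tuple[tuple[sp.Rational, ...], ...]

    def verify(self, generators: Sequence[sp.Expr]) -> bool:
        return all(
            sp.expand(sum(c * g for c, g in zip(v, generators))) == 0
            for v in self.linear_syzygies
        )


def linear_syzygies(
    generators: Sequence[sp.Expr], variables: Sequence[sp.Symbol]
) -> SyzygyReport:
    """Constant vectors ``v`` with ``sum(vi * fi)`` identically zero.

    These are the mass conservation laws of the dynamics.  The generators
    are expanded over monomials in ``variables`` jointly with parameter
    monomials, and the left null space of the resulting rational matrix is
    returned.
    """
    columns: dict[tuple, int] = {}
    rows: list[dict[int, sp.Rational]] = []
    for g in generators:
        row: dict[int, sp.Rational] = {}
        poly = sp.Poly(sp.expand(g), *variables)
        for monom, coeff in poly.terms():
            params = sorted(coeff.free_symbols, key=lambda s: s.name)
            cpoly = sp.Poly(coeff, *params) if params else None
            terms = cpoly.terms() if cpoly is not None else [((), coeff)]
            for pmon, c in terms:
                key = (monom, tuple(zip([p.name for p in params], pmon)))
                j = columns.setdefault(key, len(columns))
                row[j] = row.get(j, sp.Integer(0)) + c
        rows.append(row)
    mat = sp.zeros(len(rows), max(len(columns), 1))
    for i, row in enumerate(rows):
        for j, c in row.items():
            mat[i, j] = c
    basis = mat.T.nullspace()
    return SyzygyReport(
        tuple(tuple(v) for v in (tuple(b) for b in basis))
    )


def dynamic_stoichiometry_syzygies(crn: CRN) -> SyzygyReport:
    """Equivalent computation from the dynamic stoichiometric matrix."""
    mat = sp.Matrix(stoichiometry_matrix(crn, crn.dynamic_species))
    return SyzygyReport(tuple(tuple(b) for b in mat.T.nullspace()))


@dataclass(frozen=True)
class RpaReport:
    """Full RPA summary of a CRN with a single chemostatted input."""

    input: str
    rpa_species: Mapping[str, sp.Expr]  # species -> parameter-only setpoint
    non_rpa_species: tuple[str, ...]
    elimination_generators: Mapping[str, tuple[sp.Expr, ...]]
    certificate: LiftCertificate | None
    integral_variable: sp.Expr | None
    syzygies: SyzygyReport

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "rpa_species": {
                k: sp.sstr(sp.factor(v)) for k, v in self.rpa_species.items()
            },
            "non_rpa_species": list(self.non_rpa_species),
            "elimination_generators": {
                k: [sp.sstr(g) for g in v]
                for k, v in self.elimination_generators.items()
            },
            "lift_coefficients": None
            if self.certificate is None
            else [sp.sstr(c) for c in self.certificate.coefficients],
            "lift_unique": None if self.certificate is None else self.certificate.unique,
            "integral_variable": None
            if self.integral_variable is None
            else sp.sstr(self.integral_variable),
            "n_linear_syzygies": len(self.syzygies.linear_syzygies),
        }


def rpa_report(
    crn: CRN,
    odes: OdeSystem | None = None,
    verify_seeds: int = 0,
) -> RpaReport:
    """Screen every dynamic species for RPA against the chemostatted input.

    For each species ``X`` the two-variable elimination ideal keeping
    ``(X, input)`` is computed and classified.  A species is RPA-capable
    when a generator factors as ``g * (X - c)`` with a nonzero
    parameter-only setpoint ``c``; a zero setpoint (extinction) does not
    count as adaptation.  The lift certificate and integral variable are
    derived from the first RPA species' polynomial.
    """
    if len(crn.chemostatted) != 1:
        raise ValueError("rpa_report expects exactly one chemostatted input species")
    odes = odes or build_ode_system(crn)
    (input_sym,) = odes.inputs
    gens = steady_state_ideal(odes)
    variables = list(odes.variables) + [input_sym]

    rpa: dict[str, sp.Expr] = {}
    non_rpa: list[str] = []
    elim: dict[str, tuple[sp.Expr, ...]] = {}
    rpa_polys: list[sp.Expr] = []
    for var in odes.variables:
        ideal = elimination_ideal(
            gens, variables, [var, input_sym], verify_seeds=verify_seeds
        )
        elim[var.name] = tuple(ideal)
        found = None
        for g in ideal:
            cls = classify_rpa(
                g, var, input_sym, forbidden=[v for v in odes.variables if v != var]
            )
            if cls is not None and cls.setpoint != 0:
                found = cls
                break
        if found is None:
            non_rpa.append(var.name)
        else:
            rpa[var.name] = found.setpoint
            rpa_polys.append(found.rho)

    # The controller is identified by the RPA polynomial that lifts with
    # constant coefficients: that linear combination of rate equations is the
    # time derivative of the integral variable.
    certificate = None
    ivar = None
    syz = linear_syzygies(gens, variables)
    for target in rpa_polys:
        try:
            cert = lift_combination(
                gens, target, variables, max_degree=0, syzygies=syz
            )
        except IdealMembershipError:
            continue
        certificate = cert
        ivar = integral_variable(cert, odes.variables)
        break
    if certificate is None and rpa_polys:
        try:
            certificate = lift_combination(
                gens, rpa_polys[0], variables, syzygies=syz
            )
        except IdealMembershipError:
            certificate = None
    return RpaReport(
        input=input_sym.name,
        rpa_species=rpa,
        non_rpa_species=tuple(non_rpa),
        elimination_generators=elim,
        certificate=certificate,
        integral_variable=ivar,
        syzygies=syz,
    )
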