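"""Chemical reaction network (CRN) data model and plain-text reaction dialect.

A CRN is a list of species together with reactions between *complexes*
(multisets of species).  Species held at a fixed concentration during
dynamics — such as the extracellular lipoprotein input of the cholesterol
network — are recorded in the ``chemostatted`` set: they still participate
in the graph-theoretic structure of the network but carry no differential
equation.

The reaction dialect is one reaction per line::

    reactants "->"|"<->" products ";" key=value[, key=value]

where each side is a "+"-separated list of terms ``[multiplicity] species``
or ``0`` for the empty complex.  ``rate=`` names the rate constant of an
irreversible reaction; ``fwd=``/``rev=`` name the two rate constants of a
reversible arrow, which is stored as two irreversible reactions.  ``#``
begins a comment; ``@species`` and ``@chemostat`` are header directives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Complex",
    "Reaction",
    "CRN",
    "ParameterSet",
    "CRNError",
    "ParseError",
    "ValidationError",
    "parse_reactions",
    "serialize",
    "stoichiometry_matrix",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class CRNError(Exception):
    """Base class for CRN model errors."""


class ParseError(CRNError):
    """Malformed reaction-dialect input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ValidationError(CRNError):
    """Structurally invalid CRN component."""


@dataclass(frozen=True, order=True)
class Complex:
    """A multiset of species, canonicalized as name-sorted (species, multiplicity) pairs.

    Equality is multiset equality, so ``Ce + HR`` and ``HR + Ce`` are the
    same complex.  The empty multiset is the zero complex, written ``0`` in
    files and rendered ``∅`` in reports.
    """

    terms: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for name, mult in self.terms:
            if not _NAME_RE.match(name):
                raise ValidationError(f"invalid species name {name!r}")
            if mult <= 0:
                raise ValidationError(f"non-positive multiplicity for {name}")
        if list(self.terms) != sorted(self.terms):
            raise ValidationError("complex terms must be name-sorted; use from_terms()")
        if len({n for n, _ in self.terms}) != len(self.terms):
            raise ValidationError("duplicate species in complex terms")

    @classmethod
    def from_terms(cls, terms: Mapping[str, int] | Iterable[tuple[str, int]]) -> "Complex":
        items = dict(terms.items()) if isinstance(terms, Mapping) else {}
        if not isinstance(terms, Mapping):
            for name, mult in terms:
                items[name] = items.get(name, 0) + mult
        return cls(tuple(sorted((n, m) for n, m in items.items() if m)))

    @classmethod
    def zero(cls) -> "Complex":
        return cls(())

    @property
    def is_zero(self) -> bool:
        return not self.terms

    @property
    def support(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.terms)

    def multiplicity(self, species: str) -> int:
        return dict(self.terms).get(species, 0)

    def difference_support(self, other: "Complex") -> frozenset[str]:
        """Species whose multiplicities differ between the two complexes."""
        a, b = dict(self.terms), dict(other.terms)
        return frozenset(
            s for s in set(a) | set(b) if a.get(s, 0) != b.get(s, 0)
        )

    def to_text(self) -> str:
        if self.is_zero:
            return "0"
        return " + ".join(f"{m} {n}" if m > 1 else n for n, m in self.terms)

    def __str__(self) -> str:  # report rendering
        return "∅" if self.is_zero else self.to_text()


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction between two distinct complexes."""

    reactant: Complex
    product: Complex
    rate_symbol: str

    def __post_init__(self) -> None:
        if self.reactant == self.product:
            raise ValidationError(
                f"reaction {self.rate_symbol}: reactant equals product ({self.reactant})"
            )
        if not _NAME_RE.match(self.rate_symbol):
            raise ValidationError(f"invalid rate symbol {self.rate_symbol!r}")

    def net_stoichiometry(self, species: str) -> int:
        return self.product.multiplicity(species) - self.reactant.multiplicity(species)

    def to_text(self) -> str:
        return f"{self.reactant.to_text()} -> {self.product.to_text()} ; rate={self.rate_symbol}"

    def __str__(self) -> str:
        return f"{self.reactant} --{self.rate_symbol}--> {self.product}"


@dataclass(frozen=True)
class CRN:
    """A chemical reaction network: ordered species, ordered reactions, chemostat set."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    chemostatted: frozenset[str] = frozenset()
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species names")
        for s in self.species:
            if s == "0" or not _NAME_RE.match(s):
                raise ValidationError(f"invalid species name {s!r} ('0' is reserved)")
        known = set(self.species)
        seen_pairs: set[tuple[Complex, Complex]] = set()
        seen_rates: set[str] = set()
        for rx in self.reactions:
            for cx in (rx.reactant, rx.product):
                missing = cx.support - known
                if missing:
                    raise ValidationError(
                        f"reaction {rx.rate_symbol}: unknown species {sorted(missing)}"
                    )
            pair = (rx.reactant, rx.product)
            if pair in seen_pairs:
                raise ValidationError(f"duplicate reaction {rx.reactant} -> {rx.product}")
            seen_pairs.add(pair)
            if rx.rate_symbol in seen_rates:
                raise ValidationError(f"duplicate rate symbol {rx.rate_symbol!r}")
            seen_rates.add(rx.rate_symbol)
        if not self.chemostatted <= known:
            raise ValidationError("chemostatted set contains unknown species")

    @property
    def dynamic_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s not in self.chemostatted)

    @property
    def rate_symbols(self) -> tuple[str, ...]:
        return tuple(rx.rate_symbol for rx in self.reactions)

    def subnetwork(self, reaction_indices: Sequence[int], name: str = "") -> "CRN":
        """The sub-CRN induced by a subset of reactions (0-based indices).

        Only species occurring in the selected reactions are retained,
        preserving the parent ordering; the chemostat set is intersected.
        """
        idx = list(reaction_indices)
        if len(set(idx)) != len(idx):
            raise ValidationError("duplicate reaction indices")
        rxs = tuple(self.reactions[i] for i in idx)
        used = set()
        for rx in rxs:
            used |= rx.reactant.support | rx.product.support
        return CRN(
            species=tuple(s for s in self.species if s in used),
            reactions=rxs,
            chemostatted=frozenset(self.chemostatted & used),
            name=name,
        )


@dataclass(frozen=True)
class ParameterSet:
    """Positive rate-constant values plus the level of the chemostatted input."""

    values: Mapping[str, float]
    input_level: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        for k, v in self.values.items():
            if not v > 0:
                raise ValidationError(f"rate {k} must be positive, got {v}")
        if not self.input_level > 0:
            raise ValidationError("input level must be positive")

    def require_complete(self, crn: CRN) -> None:
        missing = set(crn.rate_symbols) - set(self.values)
        if missing:
            raise ValidationError(f"missing rate values for {sorted(missing)}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------------------
# reaction dialect

def _parse_complex(text: str, line: int) -> Complex:
    text = text.strip()
    if text == "0":
        return Complex.zero()
    terms: list[tuple[str, int]] = []
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            mult, name = 1, parts[0]
        elif len(parts) == 2:
            try:
                mult = int(parts[0])
            except ValueError:
                raise ParseError(f"bad multiplicity in term {term.strip()!r}", line)
            name = parts[1]
        else:
            raise ParseError(f"bad complex term {term.strip()!r}", line)
        if not _NAME_RE.match(name):
            raise ParseError(f"bad species name {name!r}", line)
        if mult <= 0:
            raise ParseError(f"non-positive multiplicity in {term.strip()!r}", line)
        terms.append((name, mult))
    return Complex.from_terms(terms)


def _parse_keys(text: str, line: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.split(","):
        if "=" not in item:
            raise ParseError(f"expected key=value, got {item.strip()!r}", line)
        k, v = (p.strip() for p in item.split("=", 1))
        if k in out:
            raise ParseError(f"repeated key {k!r}", line)
        out[k] = v
    return out


def parse_reactions(text: str, name: str = "") -> CRN:
    """Parse the reaction dialect into a :class:`CRN`.

    Reversible arrows expand, in file order, into the forward followed by
    the reverse irreversible reaction.  Species order follows an optional
    ``@species`` directive, otherwise first appearance.
    """
    declared: list[str] | None = None
    chemostat: list[str] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        if stripped.startswith("@"):
            parts = stripped.replace(",", " ").split()
            if parts[0] == "@species":
                declared = parts[1:]
            elif parts[0] == "@chemostat":
                chemostat.extend(parts[1:])
            else:
                raise ParseError(f"unknown directive {parts[0]!r}", lineno)
            continue
        body, _, keytext = stripped.partition(";")
        if not keytext.strip():
            raise ParseError("missing ';' rate annotation", lineno)
        keys = _parse_keys(keytext, lineno)
        if "<->" in body:
            lhs, rhs = body.split("<->", 1)
            reversible = True
        elif "->" in body:
            lhs, rhs = body.split("->", 1)
            reversible = False
        else:
            raise ParseError("missing reaction arrow", lineno)
        reactant = _parse_complex(lhs, lineno)
        product = _parse_complex(rhs, lineno)
        try:
            if reversible:
                if set(keys) != {"fwd", "rev"}:
                    raise ParseError("reversible reaction needs fwd= and rev=", lineno)
                reactions.append(Reaction(reactant, product, keys["fwd"]))
                reactions.append(Reaction(product, reactant, keys["rev"]))
            else:
                if set(keys) != {"rate"}:
                    raise ParseError("irreversible reaction needs rate=", lineno)
                reactions.append(Reaction(reactant, product, keys["rate"]))
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from exc

    appearing: list[str] = []
    for rx in reactions:
        for cx in (rx.reactant, rx.product):
            for s, _ in cx.terms:
                if s not in appearing:
                    appearing.append(s)
    if declared is None:
        species = appearing + [s for s in chemostat if s not in appearing]
    else:
        species = list(declared) + [s for s in appearing if s not in declared]
    return CRN(
        species=tuple(species),
        reactions=tuple(reactions),
        chemostatted=frozenset(chemostat),
        name=name,
    )


def serialize(crn: CRN) -> str:
    """Write a CRN in the reaction dialect; inverse of :func:`parse_reactions`."""
    lines = []
    if crn.species:
        lines.append("@species " + " ".join(crn.species))
    if crn.chemostatted:
        lines.append("@chemostat " + " ".join(s for s in crn.species if s in crn.chemostatted))
    lines.extend(rx.to_text() for rx in crn.reactions)
    return "\n".join(lines) + "\n"


def stoichiometry_matrix(
    crn: CRN, species: Sequence[str] | None = None
) -> np.ndarray:
    """Integer net-stoichiometry matrix, species x reactions.

    ``species`` defaults to all species of the CRN; pass
    ``crn.dynamic_species`` for the matrix governing the dynamics.
    """
    sps = list(crn.species if species is None else species)
    mat = np.zeros((len(sps), len(crn.reactions)), dtype=int)
    for j, rx in enumerate(crn.reactions):
        for i, s in enumerate(sps):
            mat[i, j] = rx.net_stoichiometry(s)
    return mat
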