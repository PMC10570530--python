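"""Graph-theoretic CRN invariants and the Shinar-Feinberg robustness screen.

The complex graph of a CRN has the distinct reactant/product multisets as
vertices and the reactions as directed edges.  From it we compute the
classical invariants of chemical reaction network theory: the complex count
``m``, the linkage classes (weakly connected components, ``l`` of them),
the strong linkage classes (strongly connected components) and which of
them are terminal, the exact stoichiometric rank ``s``, and the deficiency
``delta = m - l - s``.

A deficiency-one network whose non-terminal complexes include two that
differ in a single species exhibits absolute concentration robustness in
that species (Shinar-Feinberg); :func:`shinar_feinberg_screen` enumerates
every such witness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import sympy as sp

from .crn import CRN, Complex, ValidationError, stoichiometry_matrix

__all__ = [
    "GraphSummary",
    "SubnetworkPartition",
    "DecompositionReport",
    "ShinarFeinbergResult",
    "enumerate_complexes",
    "complex_graph",
    "linkage_classes",
    "strong_linkage_classes",
    "stoichiometric_rank",
    "deficiency",
    "verify_independent_decomposition",
    "shinar_feinberg_screen",
]


def enumerate_complexes(crn: CRN) -> list[Complex]:
    """Distinct complexes of the CRN, in order of first appearance."""
    seen: list[Complex] = []
    for rx in crn.reactions:
        for cx in (rx.reactant, rx.product):
            if cx not in seen:
                seen.append(cx)
    return seen


def complex_graph(crn: CRN) -> nx.MultiDiGraph:
    """Directed multigraph on complexes; edge keys are reaction indices."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(enumerate_complexes(crn))
    for i, rx in enumerate(crn.reactions):
        g.add_edge(rx.reactant, rx.product, key=i, rate=rx.rate_symbol)
    return g


def _sorted_classes(
    crn: CRN, classes: Sequence[set[Complex]]
) -> list[tuple[Complex, ...]]:
    order = {cx: i for i, cx in enumerate(enumerate_complexes(crn))}
    out = [tuple(sorted(c, key=order.__getitem__)) for c in classes]
    return sorted(out, key=lambda c: order[c[0]])


def linkage_classes(crn: CRN) -> list[tuple[Complex, ...]]:
    """Weakly connected components of the complex graph, deterministic order."""
    return _sorted_classes(crn, nx.weakly_connected_components(complex_graph(crn)))


def strong_linkage_classes(
    crn: CRN,
) -> list[tuple[tuple[Complex, ...], bool]]:
    """Strongly connected components with a terminal flag.

    A strong linkage class is terminal when no reaction leaves it.
    """
    g = complex_graph(crn)
    sccs = _sorted_classes(crn, nx.strongly_connected_components(g))
    out = []
    for scc in sccs:
        members = set(scc)
        terminal = all(
            target in members
            for cx in scc
            for target in g.successors(cx)
        )
        out.append((scc, terminal))
    return out


def stoichiometric_rank(crn: CRN) -> int:
    """Exact rank of the species x reactions net-stoichiometry matrix.

    All species are included (chemostatting plays no role in the graph
    invariants); the rank is computed in rational arithmetic.
    """
    return int(sp.Matrix(stoichiometry_matrix(crn)).rank())


@dataclass(frozen=True)
class GraphSummary:
    """Complex-graph invariants of a CRN: m, l, s and delta = m - l - s."""

    m: int
    l: int
    s: int
    deficiency: int
    linkage_classes: tuple[tuple[Complex, ...], ...]
    strong_classes: tuple[tuple[Complex, ...], ...]
    terminal_classes: tuple[tuple[Complex, ...], ...]
    nonterminal_complexes: tuple[Complex, ...]

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "l": self.l,
            "s": self.s,
            "deficiency": self.deficiency,
            "linkage_classes": [[str(c) for c in lc] for lc in self.linkage_classes],
            "terminal_classes": [[str(c) for c in tc] for tc in self.terminal_classes],
            "nonterminal_complexes": [str(c) for c in self.nonterminal_complexes],
        }


def deficiency(crn: CRN) -> GraphSummary:
    """Assemble the full graph summary of a CRN."""
    complexes = enumerate_complexes(crn)
    lcs = tuple(linkage_classes(crn))
    sccs = strong_linkage_classes(crn)
    s = stoichiometric_rank(crn)
    terminal = tuple(scc for scc, t in sccs if t)
    terminal_members = {cx for tc in terminal for cx in tc}
    nonterminal = tuple(cx for cx in complexes if cx not in terminal_members)
    m, l = len(complexes), len(lcs)
    return GraphSummary(
        m=m,
        l=l,
        s=s,
        deficiency=m - l - s,
        linkage_classes=lcs,
        strong_classes=tuple(scc for scc, _ in sccs),
        terminal_classes=terminal,
        nonterminal_complexes=nonterminal,
    )


@dataclass(frozen=True)
class SubnetworkPartition:
    """Named, disjoint, exhaustive assignment of a CRN's reactions."""

    blocks: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", {k: tuple(v) for k, v in dict(self.blocks).items()}
        )

    def validate(self, crn: CRN) -> None:
        all_idx = [i for idx in self.blocks.values() for i in idx]
        if sorted(all_idx) != list(range(len(crn.reactions))):
            raise ValidationError(
                "partition must assign every reaction exactly once"
            )


@dataclass(frozen=True)
class DecompositionReport:
    """Independence check for a reaction partition.

    Subnetworks are algebraically independent when their stoichiometric
    ranks sum to the rank of the parent network.
    """

    summaries: Mapping[str, GraphSummary]
    parent_rank: int
    rank_sum: int
    independent: bool

    def to_dict(self) -> dict:
        return {
            "parent_rank": self.parent_rank,
            "rank_sum": self.rank_sum,
            "independent": self.independent,
            "subnetworks": {k: v.to_dict() for k, v in self.summaries.items()},
        }


def verify_independent_decomposition(
    crn: CRN, partition: SubnetworkPartition
) -> DecompositionReport:
    """Graph summaries per subnetwork plus the rank-additivity check."""
    partition.validate(crn)
    summaries = {
        name: deficiency(crn.subnetwork(idx, name=name))
        for name, idx in partition.blocks.items()
    }
    parent = stoichiometric_rank(crn)
    rank_sum = sum(s.s for s in summaries.values())
    return DecompositionReport(
        summaries=summaries,
        parent_rank=parent,
        rank_sum=rank_sum,
        independent=rank_sum == parent,
    )


@dataclass(frozen=True)
class ShinarFeinbergResult:
    """Outcome of the deficiency-one absolute-concentration-robustness screen."""

    applicable: bool
    deficiency: int
    hits: tuple[tuple[str, tuple[Complex, Complex]], ...]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.hits)

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "deficiency": self.deficiency,
            "hits": [
                {"species": s, "witness": [str(a), str(b)]} for s, (a, b) in self.hits
            ],
        }


def shinar_feinberg_screen(crn: CRN) -> ShinarFeinbergResult:
    """Species guaranteed robust by the Shinar-Feinberg deficiency-one criterion.

    Applicable only when the network deficiency is exactly one; a hit is a
    species ``X`` such that two distinct non-terminal complexes differ only
    in ``X`` (their multiset difference has support of size one), reported
    with the witnessing pair.
    """
    summary = deficiency(crn)
    if summary.deficiency != 1:
        return ShinarFeinbergResult(False, summary.deficiency, ())
    hits: list[tuple[str, tuple[Complex, Complex]]] = []
    seen: set[str] = set()
    nts = summary.nonterminal_complexes
    for i, a in enumerate(nts):
        for b in nts[i + 1 :]:
            diff = a.difference_support(b)
            if len(diff) == 1:
                (species,) = diff
                if species not in seen:
                    seen.add(species)
                    hits.append((species, (a, b)))
    return ShinarFeinbergResult(True, 1, tuple(hits))
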