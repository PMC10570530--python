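"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: no networkx, no sympy matrix algebra — plain Python
data structures and exact Fraction arithmetic only.
"""

from __future__ import annotations

from fractions import Fraction

from crnrpa.crn import CRN


def _complex_key(cx) -> tuple:
    return tuple(sorted(cx.terms))


def count_complexes_bruteforce(crn: CRN) -> int:
    """Deduplicate reactant/product multisets by pairwise comparison."""
    seen: list[tuple] = []
    for rx in crn.reactions:
        for cx in (rx.reactant, rx.product):
            key = _complex_key(cx)
            if not any(key == other for other in seen):
                seen.append(key)
    return len(seen)


def linkage_classes_union_find(crn: CRN) -> list[frozenset]:
    """Weak connectivity via union-find on complexes."""
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for rx in crn.reactions:
        for cx in (rx.reactant, rx.product):
            parent.setdefault(_complex_key(cx), _complex_key(cx))
        union(_complex_key(rx.reactant), _complex_key(rx.product))
    groups: dict[tuple, set] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return [frozenset(g) for g in groups.values()]


def strong_components_reachability(crn: CRN) -> list[frozenset]:
    """SCCs via transitive closure: mutual reachability partition."""
    nodes: list[tuple] = []
    edges: set[tuple[tuple, tuple]] = set()
    for rx in crn.reactions:
        a, b = _complex_key(rx.reactant), _complex_key(rx.product)
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
        edges.add((a, b))
    reach = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            new = reach[b] - reach[a]
            if new:
                reach[a] |= new
                changed = True
    classes: list[frozenset] = []
    assigned: set[tuple] = set()
    for n in nodes:
        if n in assigned:
            continue
        scc = frozenset(m for m in nodes if m in reach[n] and n in reach[m])
        classes.append(scc)
        assigned |= scc
    return classes


def rank_fraction_elimination(matrix: list[list[int]]) -> int:
    """Exact rank by Gaussian elimination over Fraction."""
    rows = [[Fraction(x) for x in row] for row in matrix]
    if not rows or not rows[0]:
        return 0
    ncols = len(rows[0])
    rank = 0
    col = 0
    for col in range(ncols):
        pivot = next((i for i in range(rank, len(rows)) if rows[i][col] != 0), None)
        if pivot is None:
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pr = rows[rank]
        for i in range(len(rows)):
            if i != rank and rows[i][col] != 0:
                factor = rows[i][col] / pr[col]
                rows[i] = [a - factor * b for a, b in zip(rows[i], pr)]
        rank += 1
        if rank == len(rows):
            break
    return rank


def stoichiometry_rows(crn: CRN, dynamic_only: bool = False) -> list[list[int]]:
    species = crn.dynamic_species if dynamic_only else crn.species
    return [
        [rx.net_stoichiometry(s) for rx in crn.reactions] for s in species
    ]
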