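"""Deterministic, isomorphism-invariant atom ordering and symmetry orbits.

Atom mappers tend to reorder the atoms of the same metabolite arbitrarily
from one reaction to the next, which makes per-reaction mappings useless
for network-wide tracing. The fix is a canonical numbering: a pure function
of the molecular graph (elements, charges, bond orders) so that, e.g.,
"glutamate carbon 3" denotes the same structural atom in every reaction.

The algorithm is iterative neighborhood refinement (Morgan-style) followed
by individualization with lexicographically-smallest certificate selection:

1. Each atom starts with an invariant built from its element (carbons
   first, Hill convention), charge, summed bond order to heteroatoms
   (descending, so more oxidized carbons rank earlier), degree, and the
   sorted profile of (neighbor element, bond order).
2. Ranks are refined by repeatedly re-sorting on (rank, sorted neighbor
   rank profile) until the partition is stable.
3. If cells of tied atoms remain, each candidate in the first tied cell is
   individualized in turn; the branch whose fully refined labeling yields
   the smallest graph certificate wins. Ties among branches are, by
   construction, automorphic, so the first (smallest original index) is
   kept — symmetry is still reported explicitly via orbits.

Stereochemistry is ignored throughout: wedge/hash annotations play no role
in carbon-skeleton tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import networkx as nx

from .chem_io import ATOMIC_NUMBER, MappedReaction, Molecule
from .errors import CanonicalizationError

_MAX_AUTOMORPHISMS = 100_000


def _hill_key(element: str) -> tuple[int, str]:
    # Carbons first, hydrogens last, everything else alphabetical.
    if element == "C":
        return (0, "")
    if element == "H":
        return (2, "")
    return (1, element)


def _adjacency(m: Molecule) -> dict[int, list[tuple[int, int]]]:
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(1, m.n_atoms + 1)}
    for b in m.bonds:
        adj[b.a].append((b.b, b.order))
        adj[b.b].append((b.a, b.order))
    return adj


def _check_connected(m: Molecule, adj) -> None:
    if m.n_atoms == 0:
        raise CanonicalizationError(f"{m.name}: empty molecule")
    seen = {1}
    stack = [1]
    while stack:
        i = stack.pop()
        for j, _ in adj[i]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) != m.n_atoms:
        raise CanonicalizationError(
            f"{m.name}: structure is disconnected ({m.n_atoms - len(seen)} "
            "atoms unreachable); split fragments into separate molecules")


def _initial_keys(m: Molecule, adj) -> dict[int, tuple]:
    keys = {}
    for i in range(1, m.n_atoms + 1):
        nb = adj[i]
        hetero = sum(order for j, order in nb
                     if m.element(j) not in ("C", "H"))
        profile = tuple(sorted((-ATOMIC_NUMBER[m.element(j)], -order)
                               for j, order in nb))
        keys[i] = (_hill_key(m.element(i)), m.charge(i),
                   -hetero, -len(nb), profile)
    return keys


def _dense(keys: dict[int, tuple]) -> dict[int, int]:
    ordered = sorted(set(keys.values()))
    rank_of = {k: r for r, k in enumerate(ordered)}
    return {i: rank_of[k] for i, k in keys.items()}


def _refine(ranks: dict[int, int], adj) -> dict[int, int]:
    while True:
        keys = {i: (ranks[i],
                    tuple(sorted((ranks[j], -order) for j, order in adj[i])))
                for i in ranks}
        new = _dense(keys)
        if new == ranks:
            return ranks
        ranks = new


def _certificate(m: Molecule, ranks: dict[int, int]) -> tuple:
    pos = sorted(ranks, key=lambda i: ranks[i])
    nodes = tuple((_hill_key(m.element(i)), m.charge(i)) for i in pos)
    edges = tuple(sorted((min(ranks[b.a], ranks[b.b]),
                          max(ranks[b.a], ranks[b.b]), b.order)
                         for b in m.bonds))
    return (nodes, edges)


def _is_discrete(ranks: dict[int, int]) -> bool:
    return len(set(ranks.values())) == len(ranks)


def _search(m: Molecule, adj, ranks: dict[int, int]) -> tuple[tuple, dict[int, int]]:
    ranks = _refine(ranks, adj)
    if _is_discrete(ranks):
        return _certificate(m, ranks), ranks
    # first non-singleton cell in rank order, members by original index
    by_rank: dict[int, list[int]] = {}
    for i, r in ranks.items():
        by_rank.setdefault(r, []).append(i)
    target = min(r for r, members in by_rank.items() if len(members) > 1)
    best: tuple[tuple, dict[int, int]] | None = None
    for a in sorted(by_rank[target]):
        keys = {i: (ranks[i], 0 if i == a else 1) for i in ranks}
        cert, final = _search(m, adj, _dense(keys))
        if best is None or cert < best[0]:
            best = (cert, final)
    assert best is not None
    return best


def canonical_order(m: Molecule) -> Molecule:
    """Return a copy of ``m`` with ``canonical_order`` assigned.

    The ordering depends only on the labeled graph: any permutation of the
    input atom numbering yields the same canonical sequence of atoms (up to
    exchanges of truly automorphic atoms). Carbons always come first.
    """
    m.check()
    adj = _adjacency(m)
    _check_connected(m, adj)
    _, ranks = _search(m, adj, _dense(_initial_keys(m, adj)))
    order = tuple(sorted(ranks, key=lambda i: ranks[i]))
    return replace(m, canonical_order=order)


def reorder_to_canonical(m: Molecule) -> Molecule:
    """Rewrite ``m`` so that file order *is* canonical order.

    Atom ``k`` of the result is the atom at canonical position ``k``;
    bonds are relabeled accordingly and ``canonical_order`` becomes the
    identity. Idempotent.
    """
    mc = canonical_order(m) if m.canonical_order is None else m
    perm = {orig: k + 1 for k, orig in enumerate(mc.canonical_order)}
    atoms = [mc.atoms[orig - 1] for orig in mc.canonical_order]
    bonds = [replace(b, a=perm[b.a], b=perm[b.b]) for b in mc.bonds]
    out = Molecule(mc.name, atoms, bonds,
                   canonical_order=tuple(range(1, mc.n_atoms + 1)))
    out.check()
    return out


def canonicalize_reaction(r: MappedReaction) -> MappedReaction:
    """Re-express a reaction over canonically ordered molecules.

    Every molecule is rewritten via :func:`reorder_to_canonical` and the
    atom map is relabeled to the new indices.
    """
    perms_s, perms_p = [], []
    subs, prods = [], []
    for mol in r.substrates:
        mc = canonical_order(mol) if mol.canonical_order is None else mol
        perms_s.append({orig: k + 1 for k, orig in enumerate(mc.canonical_order)})
        subs.append(reorder_to_canonical(mc))
    for mol in r.products:
        mc = canonical_order(mol) if mol.canonical_order is None else mol
        perms_p.append({orig: k + 1 for k, orig in enumerate(mc.canonical_order)})
        prods.append(reorder_to_canonical(mc))
    atom_map = {((si, perms_s[si - 1][ai]), (pi, perms_p[pi - 1][aj]))
                for (si, ai), (pi, aj) in r.atom_map}
    return MappedReaction(r.reaction_id, subs, prods, atom_map,
                          r.reversible, set(r.external_ids))


# ---------------------------------------------------------------------------
# Symmetry


@dataclass(frozen=True)
class SymmetryOrbits:
    """Partition of atom indices into automorphism equivalence classes."""

    orbits: tuple[frozenset[int], ...]

    def orbit_of(self, i: int) -> frozenset[int]:
        for orb in self.orbits:
            if i in orb:
                return orb
        raise KeyError(i)


def _nx_graph(m: Molecule) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(m.atoms, 1):
        g.add_node(i, element=atom.element, charge=atom.charge)
    for b in m.bonds:
        g.add_edge(b.a, b.b, order=b.order)
    return g


def _automorphisms(m: Molecule) -> Iterable[dict[int, int]]:
    g = _nx_graph(m)
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge"], ["", 0])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 1)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=nm,
                                                     edge_match=em)
    for count, iso in enumerate(matcher.isomorphisms_iter()):
        if count >= _MAX_AUTOMORPHISMS:
            raise CanonicalizationError(
                f"{m.name}: automorphism group too large to enumerate")
        yield iso


def symmetry_orbits(m: Molecule) -> SymmetryOrbits:
    """Orbits of the automorphism group preserving element/charge/order.

    Two atoms share an orbit iff some automorphism exchanges them — e.g.
    the two carboxyl carbons of fumarate, whose interchangeability is what
    makes label fates through symmetric metabolites ambiguous.
    """
    if m.canonical_order is None:
        m = canonical_order(m)
    adj = _adjacency(m)
    _check_connected(m, adj)
    parent = {i: i for i in range(1, m.n_atoms + 1)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for iso in _automorphisms(m):
        for i, j in iso.items():
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i in parent:
        groups.setdefault(find(i), set()).add(i)
    orbits = tuple(sorted((frozenset(g) for g in groups.values()),
                          key=lambda o: min(o)))
    return SymmetryOrbits(orbits)


def carbon_automorphism_perms(m: Molecule) -> set[tuple[int, ...]]:
    """Automorphism group projected onto canonical carbon positions.

    Each element is a tuple ``p`` with ``p[k]`` the 0-based canonical
    carbon position that position ``k`` maps to. Always contains the
    identity; for asymmetric molecules it is the only element.
    """
    if m.canonical_order is None:
        m = canonical_order(m)
    carbons = m.canonical_carbons()
    pos_of = {orig: k for k, orig in enumerate(carbons)}
    perms: set[tuple[int, ...]] = set()
    for iso in _automorphisms(m):
        perms.add(tuple(pos_of[iso[orig]] for orig in carbons))
    return perms
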