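import itertools
import json
import random
from pathlib import Path

import pytest
from hypothesis import settings

import atomtrail as at
from atomtrail import fixtures as fx
from atomtrail.chem_io import Bond, Molecule

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def store_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("store")
    fx.build_fixture_store(d)
    return d


@pytest.fixture(scope="session")
def store(store_dir):
    return at.load_store(store_dir)


@pytest.fixture(scope="session")
def glycolysis_abc(store):
    model = at.parse_model_csv(fx.TOY_GLYCOLYSIS_CSV)
    return at.build_abc_model(model, store)


@pytest.fixture(scope="session")
def canonical_golden():
    return json.loads((DATA / "canonical_golden.json").read_text())


def permute_molecule(m: Molecule, perm: tuple[int, ...]) -> Molecule:
    """Relabel atoms: original index i becomes perm[i-1]."""
    atoms = [None] * m.n_atoms
    for old, new in enumerate(perm, 1):
        atoms[new - 1] = m.atoms[old - 1]
    bonds = [Bond(perm[b.a - 1], perm[b.b - 1], b.order) for b in m.bonds]
    return Molecule(m.name, atoms, bonds)


def all_or_sampled_permutations(n: int, limit: int, seed: int = 0):
    """Every permutation of 1..n when feasible, else a seeded sample."""
    if n <= 8:
        yield from itertools.permutations(range(1, n + 1))
        return
    rng = random.Random(seed)
    base = list(range(1, n + 1))
    for _ in range(limit):
        perm = base[:]
        rng.shuffle(perm)
        yield tuple(perm)


def brute_force_orbits(m: Molecule) -> set[frozenset[int]]:
    """Automorphism orbits by enumerating all vertex bijections (n <= 8)."""
    n = m.n_atoms
    assert n <= 8, "brute force oracle limited to 8 atoms"
    elems = [a.element for a in m.atoms]
    charges = [a.charge for a in m.atoms]
    edges = {frozenset((b.a, b.b)): b.order for b in m.bonds}
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in itertools.permutations(range(1, n + 1)):
        pm = (0,) + p
        if any(elems[i - 1] != elems[pm[i] - 1]
               or charges[i - 1] != charges[pm[i] - 1]
               for i in range(1, n + 1)):
            continue
        if any(edges.get(frozenset((pm[a], pm[b]))) != order
               for (a, b), order in ((tuple(e), o) for e, o in edges.items())):
            continue
        if len(edges) != len({frozenset((pm[a], pm[b]))
                              for e in edges for a, b in [tuple(e)]}):
            continue
        for i in range(1, n + 1):
            ri, rj = find(i), find(pm[i])
            if ri != rj:
                parent[ri] = rj
    groups = {}
    for i in range(1, n + 1):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}
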