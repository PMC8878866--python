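"""Assemble a network-wide ABC carbon atom-mapping model.

Given a user metabolic model (4-column CSV) and a mapping store, every
reaction is resolved to a stored, canonicalized atom mapping and rendered
in the ABC format: substrate carbons are lettered ``a, b, c, ...`` in
substrate order and canonical carbon order, and each product carbon
receives the letter of the substrate carbon it originates from. Because
every metabolite's carbons are numbered canonically, letter position ``k``
of a metabolite denotes the same structural atom in every reaction — which
is what makes the per-reaction strings composable into a network model.

Reactions absent from the store may carry user-supplied ABC strings
(custom reactions); zero-carbon participants of stored reactions (water,
protons, ammonia) that the user model does not list are omitted
automatically, and carbon-bearing cofactors can be omitted on request.
Molecular symmetry (e.g. the two-fold axis of fumarate) can be ignored,
expanded into explicit alternative entries, or collapsed onto an
orbit-minimal representative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import replace

from .canonical import carbon_automorphism_perms
from .chem_io import MappedReaction
from .errors import BuildError, CapacityError, StoreLookupError
from .mapping_store import MappingStore, lookup
from .model_format import (ABCEntry, ABCModel, ABCSpecies, KNOWN_NAMESPACES,
                           LETTERS, MetabolicModel, ModelReaction)
from .validation import carbon_balance

log = logging.getLogger(__name__)

_MAX_VARIANTS = 1000


def omit_metabolites(reaction: MappedReaction, names) -> MappedReaction:
    """Drop the named metabolite instances and any map pairs touching them.

    Substrate carbons whose product partner is dropped simply lose their
    letters downstream; product carbons whose substrate partner is dropped
    become orphans and later receive fresh letters. Omitting a metabolite
    that does not occur, or omitting a whole reaction side, is an error.
    """
    names = set(names)
    present = {m.name for m in reaction.substrates + reaction.products}
    missing = names - present
    if missing:
        raise BuildError(
            f"{reaction.reaction_id}: cannot omit absent metabolite(s) "
            f"{sorted(missing)}")
    keep_s = [i for i, m in enumerate(reaction.substrates, 1)
              if m.name not in names]
    keep_p = [i for i, m in enumerate(reaction.products, 1)
              if m.name not in names]
    if not keep_s or not keep_p:
        raise BuildError(
            f"{reaction.reaction_id}: omission would empty one reaction side")
    new_s = {old: new for new, old in enumerate(keep_s, 1)}
    new_p = {old: new for new, old in enumerate(keep_p, 1)}
    atom_map = {((new_s[si], ai), (new_p[pi], aj))
                for (si, ai), (pi, aj) in reaction.atom_map
                if si in new_s and pi in new_p}
    return MappedReaction(
        reaction.reaction_id,
        [reaction.substrate(i) for i in keep_s],
        [reaction.product(i) for i in keep_p],
        atom_map, reaction.reversible, set(reaction.external_ids))


def merge_custom_mapping(reaction: ModelReaction,
                         carbon_counts: dict[str, int]) -> ABCEntry:
    """Validate and accept a user-supplied ABC mapping for one reaction.

    Each metabolite's letter string must be exactly one letter per carbon
    of the canonically ordered structure (when the structure is known to
    the store; novel metabolites are taken at their word), and the letters
    must form a per-reaction bijection. This is what prevents the classic
    failure mode of hand-written ABC lines: strings of the right shape
    attached to an unknown atom ordering.
    """
    species = {"substrates": [], "products": []}
    for side, mets in (("substrates", reaction.substrates),
                       ("products", reaction.products)):
        for met in mets:
            if met.abc is None:
                raise BuildError(
                    f"{reaction.name}: custom reaction lacks ABC letters "
                    f"for {met.name!r}")
            expected = carbon_counts.get(met.name)
            if expected is not None and len(met.abc) != expected:
                raise BuildError(
                    f"{reaction.name}: {met.name} has {expected} carbons "
                    f"but the ABC string {met.abc!r} has {len(met.abc)} "
                    "letters")
            for _ in range(met.coefficient):
                species[side].append(ABCSpecies(met.name, met.abc))
    entry = ABCEntry(reaction.name, species["substrates"],
                     species["products"], reaction.reversible, "user")
    entry.check()  # duplicate letters within a side
    sub_letters = set(entry.side_letters("substrates"))
    prod_letters = set(entry.side_letters("products"))
    if len(sub_letters) == len(prod_letters) and sub_letters != prod_letters:
        raise BuildError(
            f"{reaction.name}: substrate letters {sorted(sub_letters)} and "
            f"product letters {sorted(prod_letters)} do not match")
    return entry


def _fresh_letters(used: set[str]):
    for c in LETTERS:
        if c not in used:
            used.add(c)
            yield c
    raise CapacityError("letter alphabet exhausted")


def _match_instances(model_mets, stored_names: list[str], store: MappingStore,
                     reaction_name: str, side: str) -> list[tuple[int, str]]:
    """Match model metabolites (coefficients expanded) to stored instances.

    Returns ``(stored instance number, model display name)`` in model
    order. Matching is in-order by resolved structure name.
    """
    available: dict[str, list[int]] = {}
    for inst, name in enumerate(stored_names, 1):
        available.setdefault(name, []).append(inst)
    matched = []
    for met in model_mets:
        resolved = store.resolve_metabolite(met.name, met.external_id)
        if resolved is None:
            raise BuildError(
                f"{reaction_name}: metabolite {met.name!r} is not known to "
                "the mapping store (no structure, alias or identifier)")
        if met.carbon_limit is not None:
            actual = store.molecules[resolved].carbon_count
            if actual != met.carbon_limit:
                raise BuildError(
                    f"{reaction_name}: {met.name} declared with "
                    f"{met.carbon_limit} carbons but the store moiety has "
                    f"{actual}")
        for _ in range(met.coefficient):
            pool = available.get(resolved, [])
            if not pool:
                raise BuildError(
                    f"{reaction_name}: {met.name!r} ({resolved}) not present "
                    f"(often enough) among the stored reaction's {side}")
            matched.append((pool.pop(0), met.name))
    leftovers = [(name, inst) for name, pool in available.items()
                 for inst in pool]
    carbon_leftovers = [name for name, _ in leftovers
                        if store.molecules[name].carbon_count > 0]
    if carbon_leftovers:
        raise BuildError(
            f"{reaction_name}: stored reaction {side} "
            f"{sorted(set(carbon_leftovers))} missing from the model row; "
            "omit them explicitly if intended")
    if leftovers:
        log.info("%s: auto-omitting zero-carbon %s %s", reaction_name, side,
                 sorted({n for n, _ in leftovers}))
    return matched


def _build_entry(rxn: ModelReaction, stored: MappedReaction,
                 store: MappingStore, provenance: str) -> ABCEntry:
    sub_match = _match_instances(rxn.substrates,
                                 [m.name for m in stored.substrates],
                                 store, rxn.name, "substrates")
    prod_match = _match_instances(rxn.products,
                                  [m.name for m in stored.products],
                                  store, rxn.name, "products")

    used: set[str] = set()
    fresh = _fresh_letters(used)
    letter_of: dict[tuple[int, int], str] = {}  # (stored inst, atom) -> letter
    substrates = []
    for inst, display in sub_match:
        mol = stored.substrate(inst)
        letters = []
        for atom_idx in mol.canonical_carbons():
            letter = next(fresh)
            letter_of[(inst, atom_idx)] = letter
            letters.append(letter)
        substrates.append(ABCSpecies(display, "".join(letters)))

    origin = {(pi, aj): (si, ai) for (si, ai), (pi, aj) in stored.atom_map}
    orphan = _fresh_letters(used)
    products = []
    for inst, display in prod_match:
        mol = stored.product(inst)
        letters = []
        for atom_idx in mol.canonical_carbons():
            src = origin.get((inst, atom_idx))
            if src is not None and src in letter_of:
                letters.append(letter_of[src])
            else:
                letters.append(next(orphan))
        products.append(ABCSpecies(display, "".join(letters)))

    entry = ABCEntry(rxn.name, substrates, products, rxn.reversible, provenance)
    entry.check()
    if carbon_balance(stored).carbon_balanced:
        subs = set(entry.side_letters("substrates"))
        prods = set(entry.side_letters("products"))
        if subs != prods:
            raise BuildError(
                f"{rxn.name}: letter conservation violated "
                f"({sorted(subs ^ prods)} unpaired) — stored mapping is "
                "incomplete on carbons")
    return entry


def apply_symmetry(entry: ABCEntry,
                   perms_by_name: dict[str, set[tuple[int, ...]]],
                   mode: str = "ignore") -> list[ABCEntry]:
    """Expand or collapse an entry over molecular symmetry.

    ``perms_by_name`` maps metabolite names to their automorphism-induced
    permutations of canonical carbon positions. ``expand`` emits one entry
    per distinct orbit relabeling (the original first), ``canonical`` the
    lexicographically smallest relabeling only, ``ignore`` the entry as-is.
    """
    if mode == "ignore":
        return [entry]
    if mode not in ("expand", "canonical"):
        raise ValueError(f"unknown symmetry mode {mode!r}")

    instances = ([("s", i, sp) for i, sp in enumerate(entry.substrates)]
                 + [("p", i, sp) for i, sp in enumerate(entry.products)])
    perm_sets = []
    for _, _, sp in instances:
        perms = perms_by_name.get(sp.name, {tuple(range(len(sp.letters)))})
        perm_sets.append(sorted(perms))
    total = 1
    for ps in perm_sets:
        total *= len(ps)
    if total > _MAX_VARIANTS:
        raise BuildError(
            f"{entry.reaction}: {total} symmetry variants exceed the limit")

    seen: set[tuple] = set()
    variants: list[ABCEntry] = []
    for combo in itertools.product(*perm_sets):
        subs = list(entry.substrates)
        prods = list(entry.products)
        for (side, i, sp), perm in zip(instances, combo):
            letters = sp.letters
            new = [""] * len(letters)
            for k, c in enumerate(letters):
                new[perm[k]] = c
            relabeled = ABCSpecies(sp.name, "".join(new))
            if side == "s":
                subs[i] = relabeled
            else:
                prods[i] = relabeled
        key = (tuple(s.letters for s in subs), tuple(p.letters for p in prods))
        if key in seen:
            continue
        seen.add(key)
        variants.append(replace(entry, substrates=subs, products=prods))
    # keep the unmodified entry first, then the relabelings in a stable order
    original_key = (tuple(s.letters for s in entry.substrates),
                    tuple(p.letters for p in entry.products))
    variants.sort(key=lambda e: (
        (tuple(s.letters for s in e.substrates),
         tuple(p.letters for p in e.products)) != original_key,
        tuple(s.letters for s in e.substrates),
        tuple(p.letters for p in e.products)))
    if mode == "canonical":
        best = min(variants, key=lambda e: (
            tuple(s.letters for s in e.substrates),
            tuple(p.letters for p in e.products)))
        return [best]
    return variants


def _resolve(rxn: ModelReaction, store: MappingStore) -> tuple[MappedReaction, str]:
    if rxn.external_id is None:
        raise BuildError(
            f"{rxn.name}: no identifier and no user ABC mapping — cannot "
            "resolve against the store")
    db, ident = rxn.external_id
    try:
        if db is None:
            stored = lookup(store, ident)
        elif db in KNOWN_NAMESPACES:
            stored = lookup(store, (db, ident))
        else:
            raise BuildError(
                f"{rxn.name}: identifier namespace {db!r} is not a known "
                "database and the reaction carries no user ABC mapping")
        return stored, f"{db + ':' if db else ''}{ident}"
    except StoreLookupError as exc:
        raise BuildError(f"{rxn.name}: {exc}") from exc


def build_abc_model(model: MetabolicModel, store: MappingStore, *,
                    omit: tuple[str, ...] = (), symmetry: str = "ignore",
                    allow_unbalanced: bool = False) -> ABCModel:
    """Build the ABC atom-mapping model for a metabolic model.

    ``omit`` names metabolites to strip from stored reactions before
    matching (cofactor simplification); zero-carbon participants are
    stripped automatically. ``symmetry`` is passed per-entry to
    :func:`apply_symmetry`. Carbon-unbalanced stored reactions are
    rejected unless ``allow_unbalanced``, in which case orphan product
    carbons receive fresh letters.
    """
    abc = ABCModel()
    perm_cache: dict[str, set[tuple[int, ...]]] = {}
    for rxn in model.reactions:
        if rxn.has_user_abc:
            counts = {}
            for met in rxn.substrates + rxn.products:
                resolved = store.resolve_metabolite(met.name, met.external_id)
                if resolved is not None:
                    counts[met.name] = store.molecules[resolved].carbon_count
            entries = [merge_custom_mapping(rxn, counts)]
        else:
            stored, provenance = _resolve(rxn, store)
            # balance is judged on the stored reaction as curated; an
            # imbalance *introduced* by omission below is deliberate
            if not carbon_balance(stored).carbon_balanced and not allow_unbalanced:
                raise BuildError(
                    f"{rxn.name}: stored reaction is carbon-unbalanced; "
                    "pass allow_unbalanced to keep it")
            names_here = {m.name for m in stored.substrates + stored.products}
            to_omit = names_here & set(omit)
            if to_omit:
                stored = omit_metabolites(stored, to_omit)
            entry = _build_entry(rxn, stored, store, provenance)
            if symmetry == "ignore":
                entries = [entry]
            else:
                for sp in entry.substrates + entry.products:
                    if sp.name not in perm_cache:
                        resolved = store.resolve_metabolite(sp.name)
                        if resolved is not None:
                            perm_cache[sp.name] = carbon_automorphism_perms(
                                store.molecules[resolved])
                entries = apply_symmetry(entry, perm_cache, symmetry)
        abc.entries.extend(entries)
    abc.check()
    return abc
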