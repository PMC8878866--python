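"""Positional label tracing through an ABC model, and error injection.

The tracer answers the question a stable-isotope labeling experiment asks
of a model: if carbon ``k`` of metabolite ``M`` is labeled, where does the
label sit after a given sequence of reactions? Propagation is purely
positional and deterministic — each labeled carbon follows its letter from
the substrate side of an entry to the product side. No fractional
enrichments and no flux weighting: that is the downstream job of flux
analysis software, for which this package builds the model.

``inject_error`` reproduces the cautionary experiment of swapping two
product letters in a single reaction: the result is still a well-formed,
letter-conserving model — validation cannot see it — but the label fates
change network-wide, which is exactly why mapping curation matters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import TraceError
from .model_format import ABCEntry, ABCModel, ABCSpecies

#: Pseudo-metabolite marking a carbon whose letter vanished from the
#: retained system (e.g. into an omitted cofactor); position is 0.
LOST = "<lost>"


@dataclass(frozen=True, order=True)
class LabelPosition:
    """One labeled carbon: (metabolite, instance tag, canonical position).

    The instance tag is caller-defined and preserved verbatim by the
    tracer; it distinguishes pooled instances of the same metabolite
    (e.g. the two glucose-derived pyruvate lineages) in merged views.
    """

    metabolite: str
    tag: str
    position: int


LabelState = frozenset  # of LabelPosition


def label(metabolite: str, position: int, tag: str = "1") -> LabelState:
    return frozenset({LabelPosition(metabolite, tag, position)})


def merged_view(state: LabelState) -> dict[str, list[int]]:
    """Per-metabolite positions pooled over instance tags."""
    out: dict[str, set[int]] = {}
    for pos in state:
        out.setdefault(pos.metabolite, set()).add(pos.position)
    return {k: sorted(v) for k, v in sorted(out.items())}


def _move_through(entry: ABCEntry, pos: LabelPosition) -> set[LabelPosition] | None:
    """Outcomes of one label crossing one entry, or None if not engaged."""
    sub_names = {s.name for s in entry.substrates}
    prod_names = {p.name for p in entry.products}
    if pos.metabolite in sub_names:
        from_side, to_side = entry.substrates, entry.products
    elif entry.reversible and pos.metabolite in prod_names:
        from_side, to_side = entry.products, entry.substrates
    else:
        return None
    outcomes: set[LabelPosition] = set()
    for species in from_side:
        if species.name != pos.metabolite:
            continue
        if not 1 <= pos.position <= len(species.letters):
            raise TraceError(
                f"{entry.reaction}: position {pos.position} outside "
                f"{pos.metabolite}'s {len(species.letters)} carbons")
        letter = species.letters[pos.position - 1]
        found = False
        for target in to_side:
            idx = target.letters.find(letter)
            if idx >= 0:
                outcomes.add(LabelPosition(target.name, pos.tag, idx + 1))
                found = True
        if not found:
            outcomes.add(LabelPosition(LOST, pos.tag, 0))
    return outcomes


def trace(model: ABCModel, start: LabelState, path: list[str]) -> LabelState:
    """Follow labeled carbons along an ordered reaction path.

    At each step every engaged label moves to the product carbon(s)
    sharing its letter; symmetry-expanded variant entries contribute the
    union of their fates. Labels on metabolites untouched by the step
    (e.g. CO2 released earlier) ride along unchanged. A step that engages
    no label at all is an error naming the gap. Reversible entries are
    traversed backwards when the label sits on their product side.
    """
    state = set(start)
    for step, name in enumerate(path, 1):
        try:
            entries = model.entries_for(name)
        except KeyError:
            raise TraceError(f"step {step}: reaction {name!r} not in model") \
                from None
        new_state: set[LabelPosition] = set()
        moved = False
        for pos in state:
            if pos.metabolite == LOST:
                new_state.add(pos)
                continue
            outcomes: set[LabelPosition] = set()
            for entry in entries:
                got = _move_through(entry, pos)
                if got is not None:
                    outcomes |= got
            if outcomes:
                moved = True
                new_state |= outcomes
            else:
                new_state.add(pos)
        if not moved:
            raise TraceError(
                f"step {step}: reaction {name!r} is not connected to any "
                f"labeled position ({merged_view(frozenset(state))})")
        state = new_state
    return frozenset(state)


def inject_error(model: ABCModel, reaction: str,
                 letters: tuple[str, str]) -> ABCModel:
    """Swap two letters on the product side of one reaction.

    The returned model is a copy; the entry remains letter-conserving and
    passes every well-formedness check — the error is chemical, not
    syntactic. Both letters must occur on the product side of the named
    reaction (in every symmetry variant).
    """
    x, y = letters
    out = model.copy()
    try:
        entries = out.entries_for(reaction)
    except KeyError:
        raise TraceError(f"reaction {reaction!r} not in model") from None
    for entry in entries:
        joined = entry.side_letters("products")
        for c in (x, y):
            if c not in joined:
                raise TraceError(
                    f"{reaction}: letter {c!r} does not occur on the "
                    "product side")
        if x == y:
            continue
        swap = {x: y, y: x}
        entry.products = [
            ABCSpecies(p.name,
                       "".join(swap.get(c, c) for c in p.letters))
            for p in entry.products]
    out.check()
    return out


@dataclass(frozen=True)
class Difference:
    """One diverging letter between two models (or a variant-count gap)."""

    reaction: str
    metabolite: str | None
    position: int | None
    letter_a: str | None
    letter_b: str | None


def diff_models(a: ABCModel, b: ABCModel) -> list[Difference]:
    """Letter-level differences between two models of the same network.

    Models must cover the same reaction names; symmetry variants are
    compared pairwise in order, and a differing variant count is reported
    as a single coarse difference for that reaction. Empty iff identical.
    """
    if set(a.reaction_names) != set(b.reaction_names):
        only_a = set(a.reaction_names) - set(b.reaction_names)
        only_b = set(b.reaction_names) - set(a.reaction_names)
        raise ValueError(
            f"models cover different reactions (only left: {sorted(only_a)}, "
            f"only right: {sorted(only_b)})")
    diffs: list[Difference] = []
    for name in a.reaction_names:
        ea, eb = a.entries_for(name), b.entries_for(name)
        if len(ea) != len(eb):
            diffs.append(Difference(name, None, None, None, None))
        for va, vb in zip(ea, eb):
            for side in ("substrates", "products"):
                sa = getattr(va, side)
                sb = getattr(vb, side)
                if [s.name for s in sa] != [s.name for s in sb]:
                    diffs.append(Difference(name, None, None, None, None))
                    continue
                for xa, xb in zip(sa, sb):
                    if len(xa.letters) != len(xb.letters):
                        diffs.append(Difference(name, xa.name, None,
                                                xa.letters, xb.letters))
                        continue
                    for k, (ca, cb) in enumerate(zip(xa.letters, xb.letters), 1):
                        if ca != cb:
                            diffs.append(Difference(name, xa.name, k, ca, cb))
    return diffs
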