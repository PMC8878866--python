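"""Filesystem-backed store of curated, canonicalized reaction mappings.

A store directory stands in for a hosted atom-mapping database: a set of
RXN files plus three CSV tables::

    index.csv        database, identifier, file, reversibility
    metabolites.csv  database, identifier, name          (optional)
    aliases.csv      alias, name                         (optional)

Several external identifiers (BRENDA / KEGG / MetaCyc) may point at the
same RXN file — that is the cross-database linking that lets a user model
mix identifier namespaces. On load every reaction is canonicalized (atoms
reordered to canonical order, the atom map re-expressed over the new
indices) and validated; in strict mode a store refuses to load any entry
that is carbon-unbalanced or carries a defective mapping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import chem_io
from .canonical import canonicalize_reaction
from .chem_io import MappedReaction, Molecule
from .errors import AmbiguousIdentifierError, StoreError, StoreLookupError
from .validation import validate_mapping

log = logging.getLogger(__name__)

_TRUE = {"reversible", "r", "1", "true", "yes"}
_FALSE = {"irreversible", "ir", "0", "false", "no"}


@dataclass
class MappingStore:
    reactions: dict[str, MappedReaction] = field(default_factory=dict)
    index: dict[tuple[str, str], str] = field(default_factory=dict)
    molecules: dict[str, Molecule] = field(default_factory=dict)
    metabolite_ids: dict[tuple[str, str], str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reactions)

    def resolve_metabolite(self, name: str,
                           external_id: tuple[str | None, str] | None = None
                           ) -> str | None:
        """Map a model metabolite to a store molecule name, or ``None``."""
        if external_id is not None:
            db, ident = external_id
            if db is not None:
                hit = self.metabolite_ids.get((db, ident))
                if hit:
                    return hit
            else:
                hits = {v for (d, i), v in self.metabolite_ids.items()
                        if i == ident}
                if len(hits) > 1:
                    raise AmbiguousIdentifierError(
                        f"metabolite id {ident!r} matches {sorted(hits)}")
                if hits:
                    return hits.pop()
        if name in self.molecules:
            return name
        return self.aliases.get(name)


def _read_csv(path: Path) -> list[dict[str, str]]:
    with path.open(newline="") as fh:
        return [{k.strip(): (v or "").strip() for k, v in row.items()}
                for row in csv.DictReader(fh)]


def load_store(directory: str | Path, lenient: bool = False) -> MappingStore:
    """Load, canonicalize and validate a store directory.

    Validation failures abort the load naming the offending identifiers,
    unless ``lenient`` is set (then they are logged and skipped). An
    empty directory yields an empty store.
    """
    directory = Path(directory)
    store = MappingStore()
    index_path = directory / "index.csv"
    rows = _read_csv(index_path) if index_path.exists() else []

    by_file: dict[str, list[dict[str, str]]] = {}
    for row in rows:
        missing = {"database", "identifier", "file"} - set(row)
        if missing:
            raise StoreError(f"{index_path}: missing column(s) {sorted(missing)}")
        by_file.setdefault(row["file"], []).append(row)

    failures: list[str] = []
    for filename, entries in sorted(by_file.items()):
        path = directory / filename
        if not path.exists():
            raise StoreError(f"store index references missing file {filename}")
        reaction = chem_io.read_rxn(path.read_text())
        reaction = canonicalize_reaction(reaction)
        rev_tokens = {e.get("reversibility", "").lower() for e in entries}
        rev_tokens.discard("")
        if len(rev_tokens) > 1:
            raise StoreError(
                f"{filename}: index rows disagree on reversibility")
        if rev_tokens:
            token = rev_tokens.pop()
            if token in _TRUE:
                reaction.reversible = True
            elif token in _FALSE:
                reaction.reversible = False
            else:
                raise StoreError(
                    f"{filename}: unparseable reversibility {token!r}")
        ids = {(e["database"], e["identifier"]) for e in entries}
        reaction.external_ids = ids

        report = validate_mapping(reaction)
        if not report.ok:
            label = ", ".join(f"{d}:{i}" for d, i in sorted(ids))
            problems = "; ".join(v.message for v in report.violations)
            if lenient:
                log.warning("skipping dirty store entry %s (%s)", label, problems)
                continue
            failures.append(f"{label}: {problems}")
            continue

        key = reaction.reaction_id
        store.reactions[key] = reaction
        for ident in ids:
            if ident in store.index:
                raise StoreError(f"duplicate index entry {ident}")
            store.index[ident] = key
        for mol in reaction.substrates + reaction.products:
            known = store.molecules.get(mol.name)
            if known is None:
                store.molecules[mol.name] = mol
            elif (known.atoms != mol.atoms
                  or sorted((min(b.a, b.b), max(b.a, b.b), b.order)
                            for b in known.bonds)
                  != sorted((min(b.a, b.b), max(b.a, b.b), b.order)
                            for b in mol.bonds)):
                raise StoreError(
                    f"metabolite {mol.name!r} has conflicting structures "
                    "across store entries")

    if failures:
        raise StoreError("store validation failed:\n  " + "\n  ".join(failures))

    met_path = directory / "metabolites.csv"
    if met_path.exists():
        for row in _read_csv(met_path):
            store.metabolite_ids[(row["database"], row["identifier"])] = row["name"]
    alias_path = directory / "aliases.csv"
    if alias_path.exists():
        for row in _read_csv(alias_path):
            store.aliases[row["alias"]] = row["name"]
    return store


def write_store(store: MappingStore, directory: str | Path) -> None:
    """Write a loaded store back out (RXN files + tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for key, reaction in sorted(store.reactions.items()):
        filename = f"{key}.rxn"
        (directory / filename).write_text(chem_io.write_rxn(reaction))
        rev = "reversible" if reaction.reversible else "irreversible"
        for db, ident in sorted(reaction.external_ids):
            index_rows.append([db, ident, filename, rev])
    with (directory / "index.csv").open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["database", "identifier", "file", "reversibility"])
        writer.writerows(index_rows)
    if store.metabolite_ids:
        with (directory / "metabolites.csv").open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["database", "identifier", "name"])
            for (db, ident), name in sorted(store.metabolite_ids.items()):
                writer.writerow([db, ident, name])
    if store.aliases:
        with (directory / "aliases.csv").open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["alias", "name"])
            for alias, name in sorted(store.aliases.items()):
                writer.writerow([alias, name])


def lookup(store: MappingStore, key: tuple[str, str] | str) -> MappedReaction:
    """Resolve an external identifier to a stored reaction.

    ``key`` is either ``(database, identifier)`` or a bare identifier
    searched across all namespaces; a bare identifier matching different
    reactions in different namespaces is an error listing the candidates.
    """
    if isinstance(key, tuple):
        hit = store.index.get(key)
        if hit is None:
            raise StoreLookupError(f"{key[0]}:{key[1]} not found in store")
        return store.reactions[hit]
    candidates = {(db, ident): name for (db, ident), name in store.index.items()
                  if ident == key}
    targets = set(candidates.values())
    if not candidates:
        raise StoreLookupError(f"identifier {key!r} not found in store")
    if len(targets) > 1:
        listing = ", ".join(f"{db}:{ident}" for db, ident in sorted(candidates))
        raise AmbiguousIdentifierError(
            f"identifier {key!r} is ambiguous across namespaces ({listing})")
    return store.reactions[targets.pop()]
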