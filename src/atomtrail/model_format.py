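"""The 4-column metabolic-model CSV and the ABC atom-mapping text format.

Model CSV
---------
One reaction per row, four comma-separated columns::

    reaction name, substrates, reversibility, products

Database identifiers ride in square brackets after a token, e.g.
``GLS [MetaCyc:GLUTAMIN-RXN]`` or ``glutamine [MetaCyc:GLN]``; a bare
``[ID]`` is matched against every namespace of the mapping store. Multiple
metabolites in a column are joined with ``+`` (surrounded by whitespace);
a leading integer is a stoichiometric coefficient. Reversibility accepts
``reversible | irreversible | r | ir | 1 | 0`` case-insensitively. A header
row is optional and detected by the literal ``reaction`` in the first cell.

Two extensions carry information the plain columns cannot:

* ``name (abcde)`` — user-supplied ABC letters for a custom reaction whose
  mapping is not in the store (one case-sensitive letter per carbon, in
  canonical carbon order);
* ``name {C:2}`` — a moiety restriction asserting the carbon count the
  model expects for this metabolite (e.g. acetyl-CoA limited to its
  2-carbon acetyl moiety), validated against the store structure.

ABC format
----------
One reaction per line: ``NAME: met (letters) + ... -> met (letters) + ...``
with ``<->`` for reversible reactions. Letters are case-sensitive
(``a..z`` then ``A..Z``, 52 per reaction side) and within one reaction a
letter appears at most once per side. Provenance is appended as a
``# source=...`` suffix. Lines repeating a reaction name are symmetry
variants of the same reaction.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field, replace

from .errors import CapacityError, ModelFormatError

log = logging.getLogger(__name__)

LETTERS = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"

KNOWN_NAMESPACES = ("BRENDA", "KEGG", "MetaCyc")

_TOKEN_RE = re.compile(
    r"^\s*(?:(?P<coef>\d+)\s+)?"
    r"(?P<name>[^\[\(\{]+?)"
    r"(?:\s*\[(?P<id>[^\]]+)\])?"
    r"(?:\s*\((?P<abc>[A-Za-z]*)\))?"
    r"(?:\s*\{C:?(?P<climit>\d+)\})?\s*$")

_REVERSIBLE = {"reversible", "r", "1"}
_IRREVERSIBLE = {"irreversible", "ir", "0"}


def _split_identifier(raw: str) -> tuple[str | None, str]:
    """``'MetaCyc:GLN'`` -> ('MetaCyc', 'GLN'); bare id -> (None, id)."""
    if ":" in raw:
        db, ident = raw.split(":", 1)
        return db.strip(), ident.strip()
    return None, raw.strip()


@dataclass
class ModelMetabolite:
    name: str
    external_id: tuple[str | None, str] | None = None
    coefficient: int = 1
    abc: str | None = None           # user-supplied letters, one per carbon
    carbon_limit: int | None = None  # moiety restriction


@dataclass
class ModelReaction:
    name: str
    external_id: tuple[str | None, str] | None
    substrates: list[ModelMetabolite]
    products: list[ModelMetabolite]
    reversible: bool
    row: int = 0

    @property
    def has_user_abc(self) -> bool:
        return all(m.abc is not None
                   for m in self.substrates + self.products)


@dataclass
class MetabolicModel:
    reactions: list[ModelReaction] = field(default_factory=list)

    def reaction(self, name: str) -> ModelReaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.reactions]


def _parse_token(raw: str, row: int, kind: str) -> tuple:
    m = _TOKEN_RE.match(raw)
    if not m or not m.group("name").strip():
        raise ModelFormatError(f"cannot parse {kind} token {raw!r}", row)
    ident = None
    if m.group("id") is not None:
        ident = _split_identifier(m.group("id"))
    coef = int(m.group("coef")) if m.group("coef") else 1
    if coef < 1:
        raise ModelFormatError(f"non-positive coefficient in {raw!r}", row)
    climit = int(m.group("climit")) if m.group("climit") else None
    return (m.group("name").strip(), ident, coef, m.group("abc"), climit)


def _parse_side(cell: str, row: int, kind: str) -> list[ModelMetabolite]:
    cell = cell.strip()
    if not cell:
        raise ModelFormatError(f"empty {kind} list", row)
    mets = []
    for raw in re.split(r"\s*\+\s*", cell):
        name, ident, coef, abc, climit = _parse_token(raw, row, kind)
        mets.append(ModelMetabolite(name, ident, coef, abc, climit))
    return mets


def parse_model_csv(text: str) -> MetabolicModel:
    """Parse the 4-column CSV model format.

    Raises :class:`ModelFormatError` naming the offending row for wrong
    column counts, unparseable reversibility tokens, duplicate reaction
    names, and empty substrate/product lists. An empty file yields an
    empty model with a logged warning.
    """
    model = MetabolicModel()
    reader = csv.reader(io.StringIO(text))
    seen: set[str] = set()
    n_rows = 0
    for row_no, cells in enumerate(reader, 1):
        if not cells or all(not c.strip() for c in cells):
            continue
        if row_no == 1 and cells[0].strip().lower() == "reaction":
            continue
        n_rows += 1
        if len(cells) != 4:
            raise ModelFormatError(
                f"expected 4 columns, found {len(cells)}", row_no)
        name_raw, subs_raw, rev_raw, prods_raw = cells
        name, rxn_id, coef, abc, _ = _parse_token(name_raw, row_no, "reaction name")
        if coef != 1 or abc is not None:
            raise ModelFormatError(
                f"reaction-name token {name_raw!r} cannot carry a "
                "coefficient or ABC letters", row_no)
        if name in seen:
            raise ModelFormatError(f"duplicate reaction name {name!r}", row_no)
        seen.add(name)
        rev_token = rev_raw.strip().lower()
        if rev_token in _REVERSIBLE:
            reversible = True
        elif rev_token in _IRREVERSIBLE:
            reversible = False
        else:
            raise ModelFormatError(
                f"unparseable reversibility token {rev_raw!r}", row_no)
        model.reactions.append(ModelReaction(
            name, rxn_id,
            _parse_side(subs_raw, row_no, "substrate"),
            _parse_side(prods_raw, row_no, "product"),
            reversible, row_no))
    if n_rows == 0:
        log.warning("model CSV contained no reactions")
    return model


# ---------------------------------------------------------------------------
# ABC format


@dataclass(frozen=True)
class ABCSpecies:
    name: str
    letters: str  # "" for zero-carbon species


@dataclass
class ABCEntry:
    """One reaction of an ABC model (or one symmetry variant of it)."""

    reaction: str
    substrates: list[ABCSpecies]
    products: list[ABCSpecies]
    reversible: bool = False
    provenance: str = ""

    def equation(self) -> str:
        arrow = "<->" if self.reversible else "->"
        left = " + ".join(f"{s.name} ({s.letters})" for s in self.substrates)
        right = " + ".join(f"{p.name} ({p.letters})" for p in self.products)
        return f"{left} {arrow} {right}"

    def side_letters(self, side: str) -> str:
        species = self.substrates if side == "substrates" else self.products
        return "".join(s.letters for s in species)

    def check(self) -> None:
        for side in ("substrates", "products"):
            joined = self.side_letters(side)
            if len(joined) > len(LETTERS):
                raise CapacityError(
                    f"{self.reaction}: {len(joined)} carbons on one side "
                    f"exhaust the {len(LETTERS)}-letter alphabet")
            if len(set(joined)) != len(joined):
                dup = sorted({c for c in joined if joined.count(c) > 1})
                raise ModelFormatError(
                    f"{self.reaction}: letter(s) {dup} occur twice on the "
                    f"{side} side")


@dataclass
class ABCModel:
    entries: list[ABCEntry] = field(default_factory=list)

    @property
    def reaction_names(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.reaction not in out:
                out.append(e.reaction)
        return out

    def entries_for(self, reaction: str) -> list[ABCEntry]:
        found = [e for e in self.entries if e.reaction == reaction]
        if not found:
            raise KeyError(reaction)
        return found

    def check(self) -> None:
        for e in self.entries:
            e.check()

    def copy(self) -> "ABCModel":
        return ABCModel([
            replace(e, substrates=list(e.substrates), products=list(e.products))
            for e in self.entries])


_ABC_SPECIES_RE = re.compile(r"^\s*(?P<name>.+?)\s*\((?P<letters>[A-Za-z]*)\)\s*$")


def _parse_abc_side(text: str, row: int) -> list[ABCSpecies]:
    species = []
    for raw in re.split(r"\s*\+\s*", text.strip()):
        m = _ABC_SPECIES_RE.match(raw)
        if not m:
            raise ModelFormatError(f"cannot parse ABC species {raw!r}", row)
        species.append(ABCSpecies(m.group("name"), m.group("letters")))
    return species


def parse_abc(text: str) -> ABCModel:
    """Parse ABC text back into a model; inverse of :func:`write_abc`."""
    model = ABCModel()
    for row, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        provenance = ""
        if "# source=" in line:
            line, _, provenance = line.partition("# source=")
            line = line.strip()
            provenance = provenance.strip()
        if ":" not in line:
            raise ModelFormatError("missing 'NAME:' prefix", row)
        name, _, equation = line.partition(":")
        reversible = "<->" in equation
        arrow = "<->" if reversible else "->"
        left, sep, right = equation.partition(arrow)
        if not sep:
            raise ModelFormatError("missing reaction arrow", row)
        entry = ABCEntry(name.strip(), _parse_abc_side(left, row),
                         _parse_abc_side(right, row), reversible, provenance)
        entry.check()
        model.entries.append(entry)
    return model


def write_abc(model: ABCModel) -> str:
    """Render an ABC model as text, one line per entry."""
    model.check()
    lines = []
    for e in model.entries:
        line = f"{e.reaction}: {e.equation()}"
        if e.provenance:
            line += f"  # source={e.provenance}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def write_abc_table(model: ABCModel) -> str:
    """Machine-readable variant: CSV with one row per entry."""
    model.check()
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["reaction", "equation", "reversible", "source"])
    for e in model.entries:
        writer.writerow([e.reaction, e.equation(),
                         "reversible" if e.reversible else "irreversible",
                         e.provenance])
    return buf.getvalue()
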