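"""Quality filters for reaction atom mappings.

Two checks gate whether a mapped reaction is usable in a carbon atom-mapping
model: the carbon balance (total substrate carbons must equal total product
carbons) and mapping integrity (every carbon paired exactly once, pairs
joining identical elements). Both are *reporting* operations — they never
raise on bad input, they record findings, because unbalanced or badly
mapped reactions are data to be filtered, not programming errors.

Note the deliberate asymmetry with the error-injection machinery in
:mod:`atomtrail.tracer`: an injected atom-mapping *error* is well-formed —
balanced, complete, bijective — and therefore invisible to these filters.
That is precisely why mapping errors are dangerous and why curation and
label-fate tracing exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_io import MappedReaction


@dataclass(frozen=True)
class Finding:
    code: str
    message: str


@dataclass
class ValidationReport:
    reaction_id: str
    carbon_balanced: bool
    substrate_carbons: int
    product_carbons: int
    carbons_unmapped: int = 0
    violations: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True when nothing blocks use in a model (info findings allowed)."""
        return self.carbon_balanced and not [
            v for v in self.violations if not v.code.startswith("INFO_")]

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "carbon_balanced": self.carbon_balanced,
            "substrate_carbons": self.substrate_carbons,
            "product_carbons": self.product_carbons,
            "carbons_unmapped": self.carbons_unmapped,
            "violations": [[v.code, v.message] for v in self.violations],
        }


def _element_counts(mols) -> dict[str, int]:
    counts: dict[str, int] = {}
    for m in mols:
        for a in m.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
    return counts


def carbon_balance(r: MappedReaction) -> ValidationReport:
    """Check that substrate and product carbon totals agree.

    Stoichiometry is respected implicitly: each molecule instance in the
    reaction contributes its own atoms. Imbalance in other elements is
    reported as an informational finding only — the carbon model neither
    tracks protons and water nor needs them to balance.
    """
    sc = sum(m.carbon_count for m in r.substrates)
    pc = sum(m.carbon_count for m in r.products)
    report = ValidationReport(r.reaction_id, sc == pc, sc, pc)
    if sc != pc:
        report.violations.append(Finding(
            "CARBON_IMBALANCE",
            f"{sc} substrate vs {pc} product carbons"))
    se = _element_counts(r.substrates)
    pe = _element_counts(r.products)
    for elem in sorted(set(se) | set(pe)):
        if elem in ("C", "H"):
            continue
        if se.get(elem, 0) != pe.get(elem, 0):
            report.violations.append(Finding(
                "INFO_ELEMENT_IMBALANCE",
                f"{elem}: {se.get(elem, 0)} vs {pe.get(elem, 0)}"))
    return report


def validate_mapping(r: MappedReaction) -> ValidationReport:
    """Full mapping-integrity report on top of the carbon balance.

    Flags element-mismatched pairs, duplicated endpoints, and — for
    carbon-balanced reactions — carbons on either side missing from the
    atom map. Mappings complete on carbons but silent on heteroatoms are
    accepted: the carbon model never consults heteroatom pairs.
    """
    report = carbon_balance(r)

    seen_sub: set[tuple[int, int]] = set()
    seen_prod: set[tuple[int, int]] = set()
    for (s, p) in sorted(r.atom_map):
        if s in seen_sub:
            report.violations.append(Finding(
                "DUPLICATE_ENDPOINT", f"substrate atom {s} mapped twice"))
        if p in seen_prod:
            report.violations.append(Finding(
                "DUPLICATE_ENDPOINT", f"product atom {p} mapped twice"))
        seen_sub.add(s)
        seen_prod.add(p)
        es = r.substrate(s[0]).element(s[1])
        ep = r.product(p[0]).element(p[1])
        if es != ep:
            report.violations.append(Finding(
                "ELEMENT_MISMATCH",
                f"pair {s}->{p} joins {es} with {ep}"))

    unmapped = 0
    for inst, mol in enumerate(r.substrates, 1):
        for i in mol.carbons():
            if (inst, i) not in seen_sub:
                unmapped += 1
    for inst, mol in enumerate(r.products, 1):
        for i in mol.carbons():
            if (inst, i) not in seen_prod:
                unmapped += 1
    report.carbons_unmapped = unmapped
    if unmapped and report.carbon_balanced:
        report.violations.append(Finding(
            "CARBON_UNMAPPED", f"{unmapped} carbon(s) missing from atom map"))
    return report
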