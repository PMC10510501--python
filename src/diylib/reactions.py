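"""Main-reaction rules, reactive-site scanning and pair compatibility.

The enumeration chemistry is rule-driven: each main reaction carries SMARTS
patterns for its two reagent roles and a SMIRKS transform; each side
pattern names a substructure that predicts byproducts under one or more
condition classes.  A reagent pair is allowed for a rule iff the roles
match, no side pattern on either molecule is active under the rule's
condition class, and no *other* main reaction sharing that condition class
is simultaneously possible across the pair (the ambiguity veto).  Main
reactions requiring a different additive/catalyst regime never veto - e.g.
a boronic acid does not block an amide coupling, because Suzuki chemistry
needs a Pd catalyst that is simply not present under amidation conditions.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from diylib.chem_io import StructureKey, mol_from_key, standardize, StandardizationError

logger = logging.getLogger("diylib.reactions")

MAIN_RULE_NAMES = ("amide", "ester", "snar", "buchwald", "suzuki", "sonogashira", "heck")
CONDITION_CLASSES = ("coupling_agent", "base_only", "pd_catalyst")
HALOGENS = ("F", "Cl", "Br", "I")


class RuleConfigError(ValueError):
    """Raised when the rule configuration is malformed or incomplete."""


# ---------------------------------------------------------------------------
# molecular-formula bookkeeping


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-style formula (``H2O``, ``H2BO2X``) into element counts.

    ``X`` is accepted as a placeholder for an unspecified halogen.
    """
    counts: Counter = Counter()
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def atom_counts(mol: Chem.Mol) -> Counter:
    """Element counts of a molecule including implicit hydrogens."""
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    if counts["H"] == 0:
        del counts["H"]
    return counts


def leaving_candidates(leaving_formula: str) -> list[Counter]:
    """Concrete element-count alternatives for a leaving formula.

    A formula containing the placeholder ``X`` expands over the halogens.
    """
    template = parse_formula(leaving_formula)
    if "X" not in template:
        return [template]
    out = []
    for hal in HALOGENS:
        c = Counter(template)
        n = c.pop("X")
        c[hal] += n
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# rule and side-pattern types


@dataclass
class ReactionRule:
    """A named two-reagent transform with condition class and leaving formula."""

    name: str
    role_a: str
    role_b: str
    transform: str
    condition_class: str
    leaving_formula: str
    smoke: tuple[str, str] | None = None
    _qa: Chem.Mol = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _qb: Chem.Mol = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _rxn: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.condition_class not in CONDITION_CLASSES:
            raise RuleConfigError(f"rule {self.name!r}: unknown condition class {self.condition_class!r}")
        self._qa = Chem.MolFromSmarts(self.role_a)
        self._qb = Chem.MolFromSmarts(self.role_b)
        if self._qa is None or self._qb is None:
            raise RuleConfigError(f"rule {self.name!r}: malformed role SMARTS")
        try:
            self._rxn = AllChem.ReactionFromSmarts(self.transform)
        except Exception as exc:
            raise RuleConfigError(f"rule {self.name!r}: malformed transform: {exc}") from exc
        parse_formula(self.leaving_formula)

    @property
    def query_a(self) -> Chem.Mol:
        return self._qa

    @property
    def query_b(self) -> Chem.Mol:
        return self._qb

    @property
    def reaction(self):
        return self._rxn


@dataclass
class SidePattern:
    """A byproduct-predicting substructure active under given condition classes."""

    name: str
    pattern: str
    blocks_under: frozenset[str]
    _query: Chem.Mol = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.blocks_under = frozenset(self.blocks_under)
        if not self.blocks_under:
            raise RuleConfigError(f"side pattern {self.name!r}: blocks_under must be nonempty")
        bad = self.blocks_under - set(CONDITION_CLASSES)
        if bad:
            raise RuleConfigError(f"side pattern {self.name!r}: unknown condition class(es) {sorted(bad)}")
        self._query = Chem.MolFromSmarts(self.pattern)
        if self._query is None:
            raise RuleConfigError(f"side pattern {self.name!r}: malformed SMARTS {self.pattern!r}")

    @property
    def query(self) -> Chem.Mol:
        return self._query


@dataclass(frozen=True)
class SiteReport:
    """Reactive-site scan of one molecule against a rule set.

    ``matches`` holds ``(rule_name, role, atom_indices)`` for every main-role
    hit (symmetric duplicates collapsed), ``side_hits`` holds
    ``(pattern_name, atom_indices)``.  The rule condition classes and side
    blocking sets are embedded so that pair compatibility can be decided
    from two reports alone.
    """

    molecule_key: StructureKey
    matches: tuple[tuple[str, str, tuple[int, ...]], ...]
    side_hits: tuple[tuple[str, tuple[int, ...]], ...]
    rule_classes: Mapping[str, str]
    side_blocks: Mapping[str, frozenset[str]]

    def has_role(self, rule_name: str, role: str) -> bool:
        return any(r == rule_name and ro == role for r, ro, _ in self.matches)


# ---------------------------------------------------------------------------
# loading and validation


def _default_config_text() -> str:
    return resources.files("diylib.data").joinpath("rules.yaml").read_text(encoding="utf-8")


def load_rule_set(config: str | Path | Mapping | None = None,
                  ) -> tuple[list[ReactionRule], list[SidePattern]]:
    """Load and validate a rule configuration (shipped default when ``None``).

    Every rule's transform is smoke-tested on its bundled reagent pair;
    a failing transform aborts the load.
    """
    if config is None:
        doc = yaml.safe_load(_default_config_text())
    elif isinstance(config, Mapping):
        doc = config
    else:
        doc = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    if not isinstance(doc, Mapping) or "rules" not in doc or "side_patterns" not in doc:
        raise RuleConfigError("config must define 'rules' and 'side_patterns'")
    missing = set(MAIN_RULE_NAMES) - set(doc["rules"])
    if missing:
        raise RuleConfigError(f"config lacks main reaction(s): {sorted(missing)}")
    rules = []
    for name in MAIN_RULE_NAMES:
        entry = doc["rules"][name]
        rule = ReactionRule(
            name=name,
            role_a=entry["role_a"],
            role_b=entry["role_b"],
            transform=entry["transform"],
            condition_class=entry["condition_class"],
            leaving_formula=entry["leaving_formula"],
            smoke=tuple(entry["smoke"]) if "smoke" in entry else None,
        )
        if rule.smoke is not None:
            a, b = (standardize(s) for s in rule.smoke)
            products = apply_rule(a, b, rule)
            if not products:
                raise RuleConfigError(f"rule {name!r}: smoke test {rule.smoke} produced no product")
        rules.append(rule)
    side_patterns = [
        SidePattern(name=name, pattern=entry["pattern"],
                    blocks_under=frozenset(entry["blocks_under"]))
        for name, entry in doc["side_patterns"].items()
    ]
    return rules, side_patterns


# ---------------------------------------------------------------------------
# scanning and compatibility


def _unique_matches(mol: Chem.Mol, query: Chem.Mol) -> list[tuple[int, ...]]:
    seen: set[frozenset[int]] = set()
    out: list[tuple[int, ...]] = []
    for match in mol.GetSubstructMatches(query, uniquify=True):
        fs = frozenset(match)
        if fs not in seen:
            seen.add(fs)
            out.append(tuple(match))
    return out


def scan_sites(molecule: StructureKey, rules: Sequence[ReactionRule],
               side_patterns: Sequence[SidePattern]) -> SiteReport:
    """Report every main-role and side-pattern match on a molecule."""
    mol = mol_from_key(molecule)
    matches: list[tuple[str, str, tuple[int, ...]]] = []
    for rule in rules:
        for role, query in (("a", rule.query_a), ("b", rule.query_b)):
            for atoms in _unique_matches(mol, query):
                matches.append((rule.name, role, atoms))
    side_hits: list[tuple[str, tuple[int, ...]]] = []
    for sp in side_patterns:
        for atoms in _unique_matches(mol, sp.query):
            side_hits.append((sp.name, atoms))
    matches.sort(key=lambda t: (t[0], t[1], t[2]))
    side_hits.sort(key=lambda t: (t[0], t[1]))
    return SiteReport(
        molecule_key=molecule,
        matches=tuple(matches),
        side_hits=tuple(side_hits),
        rule_classes={r.name: r.condition_class for r in rules},
        side_blocks={sp.name: sp.blocks_under for sp in side_patterns},
    )


def _rule_possible(a: SiteReport, b: SiteReport, rule_name: str) -> bool:
    return ((a.has_role(rule_name, "a") and b.has_role(rule_name, "b"))
            or (b.has_role(rule_name, "a") and a.has_role(rule_name, "b")))


def compatible(a: SiteReport, b: SiteReport, rule: ReactionRule) -> tuple[bool, str]:
    """Decide whether two molecules may react under ``rule``.

    Returns ``(allowed, reason)``; ``reason`` is empty when allowed and
    names the veto otherwise.  Both role assignments are tried.  Side
    patterns veto only when the rule's condition class is among their
    blocking classes, and other main reactions veto only when they share
    the rule's condition class (ambiguity veto).
    """
    if not _rule_possible(a, b, rule.name):
        return False, "role_mismatch"
    for report, tag in ((a, "a"), (b, "b")):
        for name, _atoms in report.side_hits:
            if rule.condition_class in report.side_blocks[name]:
                return False, f"side:{name}@{tag}"
    for other, klass in a.rule_classes.items():
        if other == rule.name or klass != rule.condition_class:
            continue
        if _rule_possible(a, b, other):
            return False, f"ambiguous:{other}"
    return True, ""


def apply_rule(a: StructureKey, b: StructureKey, rule: ReactionRule,
               max_products: int = 8) -> list[StructureKey]:
    """Generate standardized products of ``rule`` applied to a reagent pair.

    Both role orientations are run, one product is produced per distinct
    reactive-site combination, and products are deduplicated by InChI.
    Products violating the rule's mass balance, or failing sanitization,
    are dropped with a logged warning.  At most ``max_products`` products
    (in canonical-SMILES order) are returned, guarding against
    combinatorial blowup on polyfunctional reagents.
    """
    mol_a, mol_b = mol_from_key(a), mol_from_key(b)
    combined = atom_counts(mol_a) + atom_counts(mol_b)
    allowed_leaving = leaving_candidates(rule.leaving_formula)
    out: dict[str, StructureKey] = {}
    dropped = 0
    for ra, rb in ((mol_a, mol_b), (mol_b, mol_a)):
        try:
            product_sets = rule.reaction.RunReactants((ra, rb))
        except Exception:
            continue
        for prods in product_sets:
            for p in prods:
                try:
                    Chem.SanitizeMol(p)
                    key = standardize(Chem.MolToSmiles(p))
                except (StandardizationError, Exception):
                    dropped += 1
                    continue
                diff = combined - atom_counts(mol_from_key(key))
                total = sum(diff.values())
                if not any(diff == cand for cand in allowed_leaving) or total <= 0:
                    dropped += 1
                    continue
                out.setdefault(key.inchi, key)
    if dropped:
        logger.debug("rule %s on %s + %s: dropped %d invalid product(s)",
                     rule.name, a.canonical_smiles, b.canonical_smiles, dropped)
    products = sorted(out.values(), key=lambda k: k.canonical_smiles)
    return products[:max_products]
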