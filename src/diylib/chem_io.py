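"""Priced-catalog and product-library I/O with structure standardization.

Molecules are keyed by their standard InChI: two records describe the same
product iff their InChI strings are byte-identical.  Standardization keeps
the largest organic fragment (salts stripped), normalizes functional-group
drawing variants and neutralizes charges where unambiguous; tautomers are
deliberately *not* canonicalized, so identity is governed by InChI's own
tautomer conventions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger("diylib.chem_io")

RDLogger.DisableLog("rdApp.*")


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""


class CatalogError(ValueError):
    """Raised for malformed catalogs (missing price, duplicate id, no valid rows)."""


@dataclass(frozen=True)
class StructureKey:
    """Canonical identity of a molecule: standard InChI plus canonical SMILES."""

    inchi: str
    canonical_smiles: str

    def __hash__(self) -> int:  # identity is the InChI
        return hash(self.inchi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureKey):
            return NotImplemented
        return self.inchi == other.inchi


@dataclass(frozen=True)
class BuildingBlock:
    """A purchasable reagent: structure, identifier and price per gram."""

    id: str
    smiles: str
    price: float
    source_row: int = -1
    key: StructureKey = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise CatalogError(f"price must be positive for block {self.id!r}, got {self.price}")
        if self.key is None:
            object.__setattr__(self, "key", standardize(self.smiles))
            object.__setattr__(self, "smiles", self.key.canonical_smiles)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(smiles: str) -> StructureKey:
    """Standardize a SMILES string and return its :class:`StructureKey`.

    Pipeline: parse -> keep largest organic fragment -> normalize drawing
    variants (e.g. nitro forms) -> neutralize unambiguous charges ->
    canonical SMILES + standard InChI.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = rdMolStandardize.Normalize(mol)
    mol = _UNCHARGER.uncharge(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise StandardizationError(f"sanitization failed for {smiles!r}: {exc}") from exc
    can = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise StandardizationError(f"InChI generation failed for {smiles!r}")
    return StructureKey(inchi=inchi, canonical_smiles=can)


def mol_from_key(key: StructureKey) -> Chem.Mol:
    """Rebuild an RDKit molecule from a structure key (canonical SMILES route)."""
    mol = Chem.MolFromSmiles(key.canonical_smiles)
    if mol is None:  # cannot happen for keys produced by standardize()
        raise StandardizationError(f"stored canonical SMILES no longer parses: {key.canonical_smiles!r}")
    return mol


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "sdf", "smi"}:
        return suffix
    raise CatalogError(f"cannot infer catalog format from suffix {path.suffix!r}; pass format=")


def read_catalog(path: str | Path, format: str | None = None) -> list[BuildingBlock]:
    """Read a priced building-block catalog (CSV, SDF or SMILES file).

    CSV requires a header with columns ``id, smiles, price``.  SDF carries
    the price in a ``price_per_g`` property.  ``.smi`` files are
    tab-separated ``SMILES<TAB>id<TAB>price``.  Records that fail to parse
    are skipped with a logged warning; structural invariants (positive
    price, unique ids) are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    raw: list[tuple[str, str, str, int]] = []  # id, smiles, price-string, row
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = {c.strip().lower() for c in (reader.fieldnames or [])}
            for required in ("id", "smiles", "price"):
                if required not in cols:
                    raise CatalogError(f"catalog {path} lacks required column {required!r}")
            for i, row in enumerate(reader, start=2):
                row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
                raw.append((row["id"], row["smiles"], row["price"], i))
    elif fmt == "smi":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise CatalogError(
                        f"{path}:{i}: .smi catalogs need SMILES<TAB>id<TAB>price (price missing)"
                    )
                raw.append((parts[1], parts[0], parts[2], i))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: record %d unreadable, skipped", path, i)
                raw.append(("", "", "", i))
                continue
            if not mol.HasProp("price_per_g"):
                raise CatalogError(f"{path}: SDF record {i} lacks 'price_per_g' property")
            ident = mol.GetProp("id") if mol.HasProp("id") else mol.GetProp("_Name")
            raw.append((ident, Chem.MolToSmiles(mol), mol.GetProp("price_per_g"), i))
    else:
        raise CatalogError(f"unsupported catalog format {fmt!r}")

    blocks: list[BuildingBlock] = []
    seen: set[str] = set()
    skipped = 0
    for ident, smi, price_s, row in raw:
        if not smi:
            skipped += 1
            continue
        try:
            price = float(price_s)
        except ValueError as exc:
            raise CatalogError(f"row {row}: price {price_s!r} is not a number") from exc
        if price <= 0:
            raise CatalogError(f"row {row}: price must be positive, got {price}")
        if ident in seen:
            raise CatalogError(f"duplicate building-block id {ident!r}")
        try:
            key = standardize(smi)
        except StandardizationError:
            logger.warning("row %d (%s): unparseable structure %r, skipped", row, ident, smi)
            skipped += 1
            continue
        seen.add(ident)
        blocks.append(BuildingBlock(id=ident, smiles=key.canonical_smiles, price=price,
                                    source_row=row, key=key))
    if skipped:
        logger.warning("%s: skipped %d unreadable record(s)", path, skipped)
    if not blocks:
        raise CatalogError(f"catalog {path} contains no valid records")
    return blocks


def write_catalog(blocks: Sequence[BuildingBlock], path: str | Path) -> int:
    """Write blocks back out as a CSV catalog; returns record count."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "price"])
        for b in blocks:
            writer.writerow([b.id, b.smiles, repr(b.price) if b.price != int(b.price) else b.price])
    return len(blocks)


LIBRARY_COLUMNS = ["product_smiles", "inchi", "step_count", "rule_1", "rule_2", "bb_ids", "route_cost"]


def write_library(products: Iterable, path: str | Path, format: str = "csv",
                  costs: dict[str, float] | None = None) -> int:
    """Write enumerated products with route provenance.

    One row per product, using its preferred (fewest-step, then first
    recorded) route.  ``rule_2`` is empty for one-step products; ``bb_ids``
    are semicolon-joined in route order.  ``route_cost`` is taken from the
    optional ``costs`` mapping (InChI -> cost) when provided.
    """
    path = Path(path)
    products = list(products)
    n = 0
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(LIBRARY_COLUMNS)
            for rec in products:
                route = rec.preferred_route()
                rules = [s[0] for s in route.steps]
                bb_ids = route.bb_ids()
                cost = "" if not costs else costs.get(rec.key.inchi, "")
                writer.writerow([
                    rec.key.canonical_smiles, rec.key.inchi, route.step_count,
                    rules[0], rules[1] if len(rules) > 1 else "",
                    ";".join(bb_ids), cost,
                ])
                n += 1
    elif format == "smi":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in products:
                fh.write(f"{rec.key.canonical_smiles}\t{rec.key.inchi}\n")
                n += 1
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        for rec in products:
            mol = mol_from_key(rec.key)
            mol.SetProp("inchi", rec.key.inchi)
            route = rec.preferred_route()
            mol.SetProp("bb_ids", ";".join(route.bb_ids()))
            mol.SetProp("rules", ";".join(s[0] for s in route.steps))
            writer.write(mol)
            n += 1
        writer.close()
    else:
        raise ValueError(f"unsupported library format {format!r}")
    return n


def read_library_keys(path: str | Path) -> list[StructureKey]:
    """Read back the structure keys of a CSV library written by :func:`write_library`."""
    keys: list[StructureKey] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            keys.append(StructureKey(inchi=row["inchi"], canonical_smiles=row["product_smiles"]))
    return keys
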