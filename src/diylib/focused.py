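"""Focused-library classification: DEL blocks, covalent warheads,
nucleotide and amino-acid derivatives, and a PAINS-screened general set.

Labels are non-exclusive except the general screening set, which
additionally requires passing the PAINS screen and carrying none of the
unwanted reactive sites.  Amino-acid derivatives require a substituted
alpha carbon - bare glycine backbones are excluded, since they would
swamp the subset.  DEL suitability is decided by the number of main
reaction handles (2 or 3; single-handle capping blocks are computed but
excluded from reporting).  Every pattern list is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from diylib.chem_io import StructureKey, mol_from_key
from diylib.profiling import GateResult, PropertyProfile, apply_gates

logger = logging.getLogger("diylib.focused")

SUBSET_NAMES = ("nucleotide_deriv", "amino_acid_deriv", "warhead_fragment",
                "warhead_druglike", "del_2site", "del_3site", "bioactive",
                "general_screening")

# Main-reaction handle patterns, mirroring the reagent roles of the shipped
# rule set.  Each occurrence counts; symmetric duplicates collapse.
HANDLE_SMARTS: dict[str, str] = {
    "amine": ("[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);"
              "!$([NX3][NX3]);!$([NX3][OX2])]"),
    "carboxylic_acid": "[CX3](=[OX1])[OX2H1]",
    "aryl_halide": "c[F,Cl,Br,I]",
    "alcohol": "[OX2H1][CX4]",
    "thiol": "[SX2H1]",
    "boronic_acid": "[$([cX3]),$([CX3]=[CX3])][BX3]([OX2H1])[OX2H1]",
    "terminal_alkyne": "[CX2]#[CX2H1]",
    "olefin": "[CX3H2]=[CX3H1][#6]",
}

WARHEAD_SMARTS: dict[str, str] = {
    "nitrile": "[CX2]#[NX1]",
    "carbamate": "[NX3][CX3](=[OX1])[OX2][#6]",
    "boronic_acid": "[#6][BX3]([OX2H1])[OX2H1]",
    "acrylamide": "[CX3H2]=[CX3][CX3](=[OX1])[NX3]",
    "chloroacetamide": "Cl[CX4][CX3](=[OX1])[NX3]",
    "vinyl_sulfone": "[CX3]=[CX3][SX4](=[OX1])=[OX1]",
    "epoxide": "[OX2r3]1[#6r3][#6r3]1",
    "aldehyde": "[CX3H1]=[OX1]",
}

NUCLEOBASE_SMARTS: dict[str, str] = {
    "purine": "c1ncc2ncnc2n1",
    "n_substituted_purine": "c1nc2c(n1[#6])ncnc2",
    "pyrimidinone": "O=c1cc[nX3]c(n1)",  # uracil, thymine, related lactams
    "cytosine_like": "Nc1cc[nX3]c(=O)n1",
}

# alpha-amino acid backbone whose alpha carbon carries a side chain;
# the acid may be free, esterified or amidated
ALPHA_AA_SMARTS = "[NX3][CX4;H1,H0]([#6])[CX3](=[OX1])[OX2,OX1,NX3]"
GLYCINE_BACKBONE_SMARTS = "[NX3][CX4H2][CX3](=[OX1])[OX2,OX1,NX3]"

# default unwanted reactive sites for the general screening set (the
# electrophile subset of the shipped side patterns)
UNWANTED_SITE_SMARTS: dict[str, str] = {
    "aliphatic_halide": "[CX4][Cl,Br,I]",
    "acyl_halide": "[CX3](=[OX1])[F,Cl,Br,I]",
    "anhydride": "[CX3](=[OX1])[OX2][CX3](=[OX1])",
    "sulfonyl_halide": "[SX4](=[OX1])(=[OX1])[F,Cl,Br]",
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    "isothiocyanate": "[NX2]=[CX2]=[SX1]",
    "epoxide": "[OX2r3]1[#6r3][#6r3]1",
    "aziridine": "[NX3r3]1[#6r3][#6r3]1",
    "azide": "[NX2]=[NX2+]=[NX1-]",
    "diazonium": "[NX2+]#[NX1]",
    "peroxide": "[OX2][OX2]",
    "aldehyde": "[CX3H1]=[OX1]",
    "alpha_halo_carbonyl": "[CX3](=[OX1])[CX4][Cl,Br,I]",
}


def _compile(patterns: Mapping[str, str]) -> dict[str, Chem.Mol]:
    out = {}
    for name, smarts in patterns.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"malformed SMARTS for {name!r}: {smarts!r}")
        out[name] = q
    return out


_HANDLES = _compile(HANDLE_SMARTS)
_WARHEADS = _compile(WARHEAD_SMARTS)
_NUCLEOBASES = _compile(NUCLEOBASE_SMARTS)
_UNWANTED = _compile(UNWANTED_SITE_SMARTS)
_ALPHA_AA = Chem.MolFromSmarts(ALPHA_AA_SMARTS)
_GLY = Chem.MolFromSmarts(GLYCINE_BACKBONE_SMARTS)


@dataclass(frozen=True)
class SubsetCriteria:
    """Declarative criteria for one focused subset."""

    name: str
    substructure_requirements: tuple[str, ...] = ()  # SMARTS, any-of
    substructure_exclusions: tuple[str, ...] = ()
    gate: str | None = None
    site_count: int | None = None


def count_reactive_handles(molecule: StructureKey | Chem.Mol,
                           handles: Mapping[str, Chem.Mol] | None = None) -> int:
    """Number of main-reaction handle sites on a molecule.

    Each occurrence counts (a diamine has two amine handles); matches with
    identical atom sets collapse to one site.  Overlapping handles of
    different type (e.g. the carbon of an aryl halide) are distinct sites.
    """
    mol = molecule if isinstance(molecule, Chem.Mol) else mol_from_key(molecule)
    handles = handles or _HANDLES
    n = 0
    for q in handles.values():
        seen: set[frozenset[int]] = set()
        for match in mol.GetSubstructMatches(q):
            seen.add(frozenset(match))
        n += len(seen)
    return n


_PAINS_CATALOG: FilterCatalog | None = None


def _default_pains() -> FilterCatalog:
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)  # families A, B and C
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


def pains_screen(molecule: StructureKey | Chem.Mol,
                 pains_patterns: Mapping[str, str] | None = None) -> tuple[bool, list[str]]:
    """PAINS screen: ``(passed, matched_pattern_names)``.

    With ``pains_patterns=None`` the published PAINS families A/B/C (as
    shipped with RDKit's filter catalog) are used; a custom name->SMARTS
    mapping substitutes them.  An explicitly empty mapping passes
    everything with a logged warning.
    """
    mol = molecule if isinstance(molecule, Chem.Mol) else mol_from_key(molecule)
    if pains_patterns is None:
        catalog = _default_pains()
        matches = [e.GetDescription() for e in catalog.GetMatches(mol)]
        return (len(matches) == 0, matches)
    if not pains_patterns:
        logger.warning("empty PAINS pattern set: every molecule passes")
        return True, []
    queries = _compile(pains_patterns)
    matched = [name for name, q in queries.items() if mol.HasSubstructMatch(q)]
    return (len(matched) == 0, matched)


def _is_amino_acid_deriv(mol: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(_ALPHA_AA)


def _has_any(mol: Chem.Mol, queries: Mapping[str, Chem.Mol]) -> bool:
    return any(mol.HasSubstructMatch(q) for q in queries.values())


def classify(product, profile: PropertyProfile,
             gates: GateResult | None = None, *,
             reference_inchis: set[str] | None = None,
             include_bioactive: bool = False,
             pains_patterns: Mapping[str, str] | None = None,
             unwanted_sites: Mapping[str, str] | None = None) -> set[str]:
    """Assign focused-subset labels to one product.

    ``product`` is a :class:`~diylib.enumeration.ProductRecord` or a bare
    :class:`StructureKey`.  ``include_bioactive`` requires
    ``reference_inchis`` (exact-match InChI set of annotated bioactives).
    """
    key: StructureKey = getattr(product, "key", product)
    mol = mol_from_key(key)
    if gates is None:
        gates = apply_gates(profile)
    labels: set[str] = set()

    if _has_any(mol, _NUCLEOBASES):
        labels.add("nucleotide_deriv")
    if _is_amino_acid_deriv(mol):
        labels.add("amino_acid_deriv")
    if _has_any(mol, _WARHEADS):
        if gates.ro3:
            labels.add("warhead_fragment")
        if gates.ro5:
            labels.add("warhead_druglike")
    sites = count_reactive_handles(mol)
    if sites == 2:
        labels.add("del_2site")
    elif sites == 3:
        labels.add("del_3site")
    if include_bioactive:
        if reference_inchis is None:
            raise ValueError("bioactive classification requires a reference InChI set")
        if key.inchi in reference_inchis:
            labels.add("bioactive")
    unwanted = _UNWANTED if unwanted_sites is None else _compile(unwanted_sites)
    passed_pains, _hits = pains_screen(mol, pains_patterns)
    if passed_pains and not _has_any(mol, unwanted):
        labels.add("general_screening")
    return labels


def tabulate_subsets(label_sets: Iterable[set[str]]) -> dict[str, int]:
    """Count label occurrences over a library (one label set per product)."""
    counts = {name: 0 for name in SUBSET_NAMES}
    for labels in label_sets:
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def load_reference_inchis(path: str | Path) -> set[str]:
    """Read a plain-text reference set, one InChI per line; malformed lines
    are skipped with a warning count."""
    out: set[str] = set()
    bad = 0
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if not line.startswith("InChI="):
            bad += 1
            continue
        out.add(line)
    if bad:
        logger.warning("%s: skipped %d malformed reference line(s)", path, bad)
    return out
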