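"""Physicochemical profiling: a 19-descriptor panel and rule-based gates.

The panel covers size (molar mass, heavy atom count), lipophilicity
(Crippen logP), polarity (topological PSA, H-bond donors/acceptors,
O+N count, heteroatom ratio), flexibility (rotatable bonds), shape
(ring counts, fraction of sp3 carbons, chiral centers), molar
refractivity, and functional-group counts (acidic, basic, noncyclic
amide).  H-bond acceptors default to RDKit's acceptor perception; the
Lipinski N+O variant is exposed alongside.

Gates are pure threshold logic and fully configurable; the shipped
defaults are the canonical literature definitions of Lipinski's rule of
five, the rule of three for fragments (strict ``<`` on mass, ``<=``
elsewhere), and Oprea-style lead-likeness.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from diylib.chem_io import StructureKey, mol_from_key

ACIDIC_SMARTS = {
    "carboxylic_acid": "[CX3](=[OX1])[OX2H1]",
    "sulfonic_acid": "[SX4](=[OX1])(=[OX1])[OX2H1]",
    "phosphonic_acid": "[PX4](=[OX1])([OX2H1])",
    "tetrazole": "c1nnn[nH]1",
}
BASIC_SMARTS = {
    # aliphatic amines (incl. cyclic), excluding amides/sulfonamides,
    # anilines, N-N and N-O linked nitrogens
    "aliphatic_amine": ("[NX3;!$([NX3][CX3]=[OX1,NX2,SX1]);!$([NX3][a]);"
                        "!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2])]"),
    "amidine": "[NX3][CX3]=[NX2]",
    "guanidine": "[NX3][CX3](=[NX2])[NX3]",
}
NONCYCLIC_AMIDE_SMARTS = "[CX3;!R](=[OX1])[NX3;!R]"

_ACID_QUERIES = {n: Chem.MolFromSmarts(s) for n, s in ACIDIC_SMARTS.items()}
_BASE_QUERIES = {n: Chem.MolFromSmarts(s) for n, s in BASIC_SMARTS.items()}
_AMIDE_QUERY = Chem.MolFromSmarts(NONCYCLIC_AMIDE_SMARTS)


@dataclass(frozen=True)
class PropertyProfile:
    """The 19-descriptor physicochemical panel of one molecule."""

    molar_mass: float
    logp: float
    psa: float
    n_hba: int
    n_hbd: int
    n_rotb: int
    hac: int
    n_rings: int
    fsp3: float
    refractivity: float
    n_aromatic_rings: int
    n_aliphatic_rings: int
    n_chiral_centers: int
    n_acidic: int
    n_basic: int
    n_acid_base: int
    n_noncyclic_amide: int
    n_o_plus_n: int
    heteroatom_ratio: float
    n_hba_lipinski: int = 0  # N+O count, exposed alongside acceptor perception

    def to_dict(self) -> dict:
        return asdict(self)


def _count_unique(mol: Chem.Mol, queries: Mapping[str, Chem.Mol]) -> int:
    seen: set[frozenset[int]] = set()
    for q in queries.values():
        for match in mol.GetSubstructMatches(q):
            seen.add(frozenset(match))
    return len(seen)


def compute_profile(molecule: StructureKey | str) -> PropertyProfile:
    """Compute the full descriptor panel for one molecule."""
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {molecule!r}")
    else:
        mol = mol_from_key(molecule)
    ring_info = mol.GetRingInfo()
    hac = mol.GetNumHeavyAtoms()
    n_o_plus_n = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    n_acidic = _count_unique(mol, _ACID_QUERIES)
    n_basic = _count_unique(mol, _BASE_QUERIES)
    chiral = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    return PropertyProfile(
        molar_mass=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        # topological PSA with the extended S/P contributions
        psa=rdMolDescriptors.CalcTPSA(mol, includeSandP=True),
        n_hba=rdMolDescriptors.CalcNumHBA(mol),
        n_hbd=rdMolDescriptors.CalcNumHBD(mol),
        # rotatable bond: acyclic single bond between two non-terminal heavy
        # atoms, excluding bonds adjacent to triple bonds
        n_rotb=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.NonStrict),
        hac=hac,
        n_rings=ring_info.NumRings(),
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
        refractivity=Crippen.MolMR(mol),
        n_aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        n_aliphatic_rings=rdMolDescriptors.CalcNumAliphaticRings(mol),
        n_chiral_centers=len(chiral),
        n_acidic=n_acidic,
        n_basic=n_basic,
        n_acid_base=n_acidic + n_basic,
        n_noncyclic_amide=len(mol.GetSubstructMatches(_AMIDE_QUERY)),
        n_o_plus_n=n_o_plus_n,
        heteroatom_ratio=(n_hetero / hac) if hac else 0.0,
        n_hba_lipinski=n_o_plus_n,
    )


@dataclass(frozen=True)
class GateResult:
    ro3: bool
    lead_like: bool
    ro5: bool


# bounds are (low, high, low_inclusive, high_inclusive); None = unbounded
DEFAULT_GATES: dict[str, dict[str, tuple]] = {
    "ro5": {
        "molar_mass": (None, 500.0, True, True),
        "logp": (None, 5.0, True, True),
        "n_hbd": (None, 5, True, True),
        "n_hba": (None, 10, True, True),
    },
    "ro3": {
        "molar_mass": (None, 300.0, True, False),  # strict < 300
        "logp": (None, 3.0, True, True),
        "n_hbd": (None, 3, True, True),
        "n_hba": (None, 3, True, True),
        "n_rotb": (None, 3, True, True),
        "psa": (None, 60.0, True, True),
    },
    "lead_like": {
        "molar_mass": (200.0, 450.0, True, True),
        "logp": (-3.5, 4.5, True, True),
        "n_rings": (None, 4, True, True),
        "n_rotb": (None, 10, True, True),
    },
}


def _passes(profile: PropertyProfile, bounds: Mapping[str, tuple]) -> bool:
    values = profile.to_dict()
    for name, (lo, hi, lo_incl, hi_incl) in bounds.items():
        if name not in values:
            raise ValueError(f"gate references unknown descriptor {name!r}")
        v = values[name]
        if lo is not None and (v < lo or (not lo_incl and v == lo)):
            return False
        if hi is not None and (v > hi or (not hi_incl and v == hi)):
            return False
    return True


def apply_gates(profile: PropertyProfile,
                thresholds: Mapping[str, Mapping[str, tuple]] | None = None) -> GateResult:
    """Evaluate the Ro3 / lead-like / Ro5 gates for one profile."""
    gates = DEFAULT_GATES if thresholds is None else thresholds
    for required in ("ro3", "lead_like", "ro5"):
        if required not in gates:
            raise ValueError(f"thresholds lack gate {required!r}")
        for name, bound in gates[required].items():
            if len(bound) != 4:
                raise ValueError(f"gate {required!r}/{name!r}: bounds must be "
                                 "(low, high, low_inclusive, high_inclusive)")
    return GateResult(
        ro3=_passes(profile, gates["ro3"]),
        lead_like=_passes(profile, gates["lead_like"]),
        ro5=_passes(profile, gates["ro5"]),
    )
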