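"""Descriptor panel and gate logic, with a cross-implementation oracle.

The integer descriptors are re-derived by an independent graph-walking
implementation (no RDKit descriptor calls); the continuous descriptors
(molar mass, logP, PSA, molar refractivity) are compared against
OpenBabel's ``obprop`` output within a documented +/-15% band.
"""

import shutil
import subprocess
import tempfile

import pytest
from rdkit import Chem

from diylib.chem_io import standardize
from diylib.profiling import DEFAULT_GATES, PropertyProfile, apply_gates, compute_profile

# a 50-molecule drug-like reference panel: common drugs, fragments and
# reagents whose descriptor values are uncontroversial between established
# estimators (no charge-separated or exotic-parameter functionality)
PANEL = [
    "CC(=O)Nc1ccc(O)cc1", "CC(=O)Oc1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "CN(C)C(=O)c1ccccc1", "OC(=O)c1ccccc1O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Clc1ccccc1", "Oc1ccccc1", "COc1ccc(CCO)cc1",
    "CCN(CC)CC", "CC(=O)NC(C)Cc1ccccc1", "OCC(O)CO", "CC(=O)CC(=O)C", "O=C1CCCCC1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
    "CC(C)(C)OC(=O)N1CCCC1", "COc1ccccc1", "OC1CCCCC1", "OC(=O)CCCCC(=O)O",
    "CSc1ccccc1", "FC(F)(F)c1ccccc1", "COC(=O)c1ccccc1", "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1", "Ic1ccccc1", "Brc1ccncc1", "OB(O)c1ccccc1",
    "C=Cc1ccccc1", "C#Cc1ccccc1", "OCCOCCO", "CC1CCCCC1O", "CC(O)c1ccccc1",
    "O=C(O)c1cccnc1", "Nc1ncnc2[nH]cnc12", "Cc1ccc(C(=O)O)cc1",
    "CC(=O)NC(Cc1ccccc1)C(=O)O", "CC(C)CC(=O)O", "OC(=O)C1CCCN1",
    "O=c1cc[nH]c(=O)[nH]1", "Cn1ccnc1", "C1CCNCC1", "C1COCCN1", "O=C1CCCN1",
    "CC(C)(C)c1ccc(O)cc1", "CCCCCCCC",
]


def independent_integer_descriptors(smiles: str) -> dict:
    """Graph-walking re-derivation of the integer panel descriptors."""
    mol = Chem.MolFromSmiles(smiles)
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    hac = len(heavy)
    n_on = sum(1 for a in heavy if a.GetAtomicNum() in (7, 8))
    n_het = sum(1 for a in heavy if a.GetAtomicNum() != 6)
    # cyclomatic ring count: bonds - atoms + connected components
    n_rings = mol.GetNumBonds() - mol.GetNumAtoms() + len(Chem.GetMolFrags(mol))
    n_hbd = sum(1 for a in heavy
                if a.GetAtomicNum() in (7, 8, 16) and a.GetTotalNumHs() > 0)
    n_rotb = 0
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE or b.IsInRing():
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if a1.GetDegree() < 2 or a2.GetDegree() < 2:
            continue
        if any(nb.GetBondType() == Chem.BondType.TRIPLE
               for a in (a1, a2) for nb in a.GetBonds()):
            continue
        n_rotb += 1
    carbons = [a for a in heavy if a.GetAtomicNum() == 6]
    sp3 = sum(1 for a in carbons
              if not a.GetIsAromatic()
              and all(b.GetBondType() == Chem.BondType.SINGLE for b in a.GetBonds()))
    return {
        "hac": hac, "n_o_plus_n": n_on, "n_rings": n_rings, "n_hbd": n_hbd,
        "n_rotb": n_rotb, "n_hba_lipinski": n_on,
        "heteroatom_ratio": n_het / hac,
        "fsp3": sp3 / len(carbons) if carbons else 0.0,
    }


def obprop_values(smiles_list):
    """Continuous descriptors from OpenBabel's obprop, keyed by title."""
    exe = shutil.which("obprop")
    if exe is None:
        pytest.skip("obprop not on PATH")
    payload = "".join(f"{s} m{i}\n" for i, s in enumerate(smiles_list))
    with tempfile.NamedTemporaryFile("w", suffix=".smi", delete=False) as fh:
        fh.write(payload)
        name = fh.name
    proc = subprocess.run([exe, name], text=True, capture_output=True, check=False)
    out = {}
    current = None
    for line in proc.stdout.splitlines():
        parts = line.split()
        if len(parts) < 2:
            continue
        if parts[0] == "name":
            current = parts[1]
            out[current] = {}
        elif current is not None and parts[0] in ("mol_weight", "logP", "PSA", "MR"):
            out[current][parts[0]] = float(parts[1])
    return out


class TestComputeProfile:
    def test_benzene(self):
        p = compute_profile(standardize("c1ccccc1"))
        assert p.molar_mass == pytest.approx(78.11, abs=0.01)
        assert p.hac == 6 and p.n_aromatic_rings == 1 and p.fsp3 == 0.0
        assert p.n_hbd == 0 and p.heteroatom_ratio == 0.0

    def test_ethane(self):
        p = compute_profile(standardize("CC"))
        assert p.fsp3 == 1.0 and p.n_rings == 0 and p.n_rotb == 0

    def test_n_methylacetamide(self):
        p = compute_profile(standardize("CNC(C)=O"))
        assert p.n_noncyclic_amide == 1
        assert p.n_o_plus_n == 2
        assert p.heteroatom_ratio == pytest.approx(2 / 5)  # 2 of 5 heavy atoms

    def test_acid_base_counts(self):
        p = compute_profile(standardize("NCCCCC(N)C(=O)O"))  # lysine
        assert p.n_acidic == 1 and p.n_basic == 2 and p.n_acid_base == 3

    def test_invariant_under_smiles_renumbering(self):
        a = compute_profile(standardize("CC(=O)Oc1ccccc1C(=O)O"))
        b = compute_profile(standardize("OC(=O)c1ccccc1OC(C)=O"))
        assert a == b

    def test_integer_descriptors_match_independent_implementation(self):
        for smi in PANEL:
            profile = compute_profile(standardize(smi)).to_dict()
            oracle = independent_integer_descriptors(standardize(smi).canonical_smiles)
            for name, want in oracle.items():
                if name in ("heteroatom_ratio", "fsp3"):
                    assert profile[name] == pytest.approx(want), (smi, name)
                else:
                    assert profile[name] == want, (smi, name)
            assert profile["n_hba"] <= profile["n_hba_lipinski"] + 1  # perception bound

    def test_continuous_descriptors_match_openbabel(self):
        keys = [standardize(s) for s in PANEL]
        ob = obprop_values([k.canonical_smiles for k in keys])
        assert len(ob) == len(PANEL)
        checked = 0
        for i, key in enumerate(keys):
            vals = ob[f"m{i}"]
            p = compute_profile(key)
            assert p.molar_mass == pytest.approx(vals["mol_weight"], rel=0.01)
            for ours, theirs in ((p.logp, vals["logP"]), (p.psa, vals["PSA"]),
                                 (p.refractivity, vals["MR"])):
                assert ours == pytest.approx(theirs, rel=0.15, abs=0.6), (PANEL[i],)
            checked += 1
        assert checked == len(PANEL)


class TestGates:
    def _profile(self, **over):
        base = dict(molar_mass=250.0, logp=2.0, psa=50.0, n_hba=3, n_hbd=1,
                    n_rotb=3, hac=18, n_rings=2, fsp3=0.3, refractivity=70.0,
                    n_aromatic_rings=1, n_aliphatic_rings=1, n_chiral_centers=0,
                    n_acidic=0, n_basic=0, n_acid_base=0, n_noncyclic_amide=1,
                    n_o_plus_n=4, heteroatom_ratio=0.2, n_hba_lipinski=4)
        base.update(over)
        return PropertyProfile(**base)

    def test_heavy_molecule_fails_ro5(self):
        assert not apply_gates(self._profile(molar_mass=600.0)).ro5

    def test_benzene_passes_ro5_and_ro3(self):
        gates = apply_gates(compute_profile(standardize("c1ccccc1")))
        assert gates.ro5 and gates.ro3

    def test_ro3_boundary_semantics(self):
        # mass strictly < 300; every other bound inclusive
        at_limits = self._profile(molar_mass=299.0, logp=3.0, n_hbd=3, n_hba=3,
                                  n_rotb=3, psa=60.0)
        assert apply_gates(at_limits).ro3
        assert not apply_gates(self._profile(molar_mass=300.0, logp=3.0, n_hbd=3,
                                             n_hba=3, n_rotb=3, psa=60.0)).ro3

    def test_lead_like_window(self):
        assert apply_gates(self._profile(molar_mass=200.0)).lead_like
        assert not apply_gates(self._profile(molar_mass=199.9)).lead_like
        assert not apply_gates(self._profile(logp=4.6)).lead_like

    def test_ro3_implies_ro5_on_panel(self):
        for smi in PANEL:
            gates = apply_gates(compute_profile(standardize(smi)))
            if gates.ro3:
                assert gates.ro5, smi

    def test_malformed_thresholds(self):
        with pytest.raises(ValueError):
            apply_gates(self._profile(), thresholds={"ro3": {}, "ro5": {}})
        bad = {k: dict(v) for k, v in DEFAULT_GATES.items()}
        bad["ro5"] = {"molar_mass": (None, 500.0)}
        with pytest.raises(ValueError):
            apply_gates(self._profile(), thresholds=bad)
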