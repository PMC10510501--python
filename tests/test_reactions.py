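"""Reaction rules: loading, site scanning, pair compatibility, products."""

import copy
import random

import pytest

from diylib.chem_io import standardize
from diylib.reactions import (MAIN_RULE_NAMES, RuleConfigError, apply_rule,
                              atom_counts, compatible, leaving_candidates,
                              load_rule_set, parse_formula, scan_sites)
from diylib.chem_io import mol_from_key
from diylib.fixtures import CatalogSpec, generate_catalog


def rule_by_name(rules, name):
    return next(r for r in rules if r.name == name)


class TestLoadRuleSet:
    def test_default_config_contract(self, rule_set):
        rules, sides = rule_set
        assert {r.name for r in rules} == set(MAIN_RULE_NAMES)
        assert len(sides) >= 20
        assert all(sp.blocks_under for sp in sides)

    def test_missing_rule_is_error(self, config_dict):
        cfg = copy.deepcopy(config_dict)
        del cfg["rules"]["heck"]
        with pytest.raises(RuleConfigError, match="heck"):
            load_rule_set(cfg)

    def test_empty_blocks_under_is_error(self, config_dict):
        cfg = copy.deepcopy(config_dict)
        cfg["side_patterns"]["aliphatic_halide"]["blocks_under"] = []
        with pytest.raises(RuleConfigError, match="blocks_under"):
            load_rule_set(cfg)

    def test_malformed_pattern_names_the_rule(self, config_dict):
        cfg = copy.deepcopy(config_dict)
        cfg["rules"]["amide"]["role_a"] = "[[["
        with pytest.raises(RuleConfigError, match="amide"):
            load_rule_set(cfg)


class TestScanSites:
    def test_carboxylic_acid_is_both_acyl_donors(self, rule_set):
        report = scan_sites(standardize("CC(=O)O"), *rule_set)
        hit_rules = {(r, role) for r, role, _ in report.matches}
        assert ("amide", "a") in hit_rules and ("ester", "a") in hit_rules

    def test_inert_aromatic_has_no_matches(self, rule_set):
        report = scan_sites(standardize("c1ccccc1"), *rule_set)
        assert report.matches == () and report.side_hits == ()

    def test_aliphatic_halide_amine_reports_both(self, rule_set):
        report = scan_sites(standardize("NCCBr"), *rule_set)
        assert report.has_role("amide", "b")
        assert any(name == "aliphatic_halide" for name, _ in report.side_hits)

    def test_symmetric_matches_collapse(self, rule_set):
        # symmetric diamine: two amine sites, not four permuted matches
        report = scan_sites(standardize("NCCN"), *rule_set)
        amine_sites = [a for r, role, a in report.matches if (r, role) == ("amide", "b")]
        assert len(amine_sites) == 2


class TestCompatible:
    def test_boronic_amine_allowed_under_amide(self, rule_set):
        # Suzuki chemistry needs a Pd catalyst absent under amidation, so a
        # boronic acid on the amine partner does not veto the coupling
        rules, sides = rule_set
        acid = scan_sites(standardize("CC(=O)O"), rules, sides)
        amine = scan_sites(standardize("NCc1ccc(B(O)O)cc1"), rules, sides)
        ok, reason = compatible(acid, amine, rule_by_name(rules, "amide"))
        assert ok, reason

    def test_aliphatic_halide_vetoes_amide(self, rule_set):
        rules, sides = rule_set
        acid = scan_sites(standardize("CC(=O)O"), rules, sides)
        amine = scan_sites(standardize("NCCBr"), rules, sides)
        ok, reason = compatible(acid, amine, rule_by_name(rules, "amide"))
        assert not ok and "aliphatic_halide" in reason

    def test_amide_ester_ambiguity_veto(self, rule_set):
        # amide and ester share the coupling-agent condition class, so an
        # amino alcohol partner is ambiguous and vetoed
        rules, sides = rule_set
        acid = scan_sites(standardize("CC(=O)O"), rules, sides)
        amino_alcohol = scan_sites(standardize("NCCO"), rules, sides)
        for rule_name in ("amide", "ester"):
            ok, reason = compatible(acid, amino_alcohol, rule_by_name(rules, rule_name))
            assert not ok and reason.startswith("ambiguous")

    def test_symmetry_under_role_swap(self, rule_set):
        rules, sides = rule_set
        mols = ["CC(=O)O", "CN", "NCCO", "Brc1ccccc1", "OB(O)c1ccccc1",
                "Clc1ccncc1", "C#Cc1ccccc1", "NCCBr"]
        reports = [scan_sites(standardize(m), rules, sides) for m in mols]
        for i in range(len(reports)):
            for j in range(len(reports)):
                for rule in rules:
                    assert compatible(reports[i], reports[j], rule)[0] == \
                        compatible(reports[j], reports[i], rule)[0]


class TestApplyRule:
    @pytest.mark.parametrize("a,b,rule_name,expected", [
        ("CC(=O)O", "CN", "amide", {"CNC(C)=O"}),
        ("Brc1ccccc1", "OB(O)c1ccccc1", "suzuki", {"c1ccc(-c2ccccc2)cc1"}),
        ("Clc1ccncc1", "CN", "snar", {"CNc1ccncc1"}),
    ])
    def test_textbook_products(self, rule_set, a, b, rule_name, expected):
        rules, _ = rule_set
        products = apply_rule(standardize(a), standardize(b), rule_by_name(rules, rule_name))
        assert {p.canonical_smiles for p in products} == expected

    def test_symmetric_diamine_products_dedupe(self, rule_set):
        rules, _ = rule_set
        products = apply_rule(standardize("NCCCN"), standardize("CC(=O)O"),
                              rule_by_name(rules, "amide"))
        assert [p.canonical_smiles for p in products] == ["CC(=O)NCCCN"]

    def test_order_independent(self, rule_set):
        rules, _ = rule_set
        a, b = standardize("CC(=O)O"), standardize("NCCCN")
        rule = rule_by_name(rules, "amide")
        assert ({p.inchi for p in apply_rule(a, b, rule)}
                == {p.inchi for p in apply_rule(b, a, rule)})

    def test_heck_product_is_e_configured(self, rule_set):
        rules, _ = rule_set
        products = apply_rule(standardize("Brc1ccccc1"), standardize("C=CCC"),
                              rule_by_name(rules, "heck"))
        assert any("/b" in p.inchi for p in products)


class TestMassBalance:
    def test_formula_arithmetic(self):
        assert parse_formula("H2O") == {"H": 2, "O": 1}
        assert parse_formula("H2BO2X") == {"H": 2, "B": 1, "O": 2, "X": 1}
        assert len(leaving_candidates("HX")) == 4

    def test_mass_balance_on_random_pairings(self, rule_set):
        """Every product's formula equals combined reagents minus the
        leaving formula (enforced inside apply_rule: a violating product
        would be dropped, so products found must balance)."""
        rules, sides = rule_set
        blocks = generate_catalog(CatalogSpec(n_blocks=25, seed=11))
        reports = {b.id: scan_sites(b.key, rules, sides) for b in blocks}
        rng = random.Random(5)
        checked = 0
        for _ in range(400):
            a, b = rng.choice(blocks), rng.choice(blocks)
            for rule in rules:
                if not compatible(reports[a.id], reports[b.id], rule)[0]:
                    continue
                combined = atom_counts(mol_from_key(a.key)) + atom_counts(mol_from_key(b.key))
                for p in apply_rule(a.key, b.key, rule):
                    diff = combined - atom_counts(mol_from_key(p))
                    assert any(diff == cand for cand in leaving_candidates(rule.leaving_formula))
                    checked += 1
        assert checked > 50  # the fixture must actually exercise reactions


def test_determinism_of_scan_and_apply(rule_set):
    rules, sides = rule_set
    key = standardize("NCc1ccc(B(O)O)cc1")
    r1 = scan_sites(key, rules, sides)
    r2 = scan_sites(key, rules, sides)
    assert r1.matches == r2.matches and r1.side_hits == r2.side_hits
    acid = standardize("CC(=O)O")
    rule = rule_by_name(rules, "amide")
    assert apply_rule(acid, key, rule) == apply_rule(acid, key, rule)
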