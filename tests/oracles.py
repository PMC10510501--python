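"""Independent naive reference implementations used as test oracles.

These deliberately avoid the package's indexed/cached code paths: the
enumerator re-scans every molecule for every ordered pair with direct
RDKit calls, and the greedy eliminator recomputes every score from
scratch at every iteration with no inverted index.
"""

from __future__ import annotations

from collections import Counter

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

HALOGENS = ("F", "Cl", "Br", "I")


def _counts(mol):
    c = Counter()
    for a in mol.GetAtoms():
        c[a.GetSymbol()] += 1
        c["H"] += a.GetTotalNumHs()
    if c["H"] == 0:
        del c["H"]
    return c


def _leaving_variants(formula: str):
    import re
    base = Counter()
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            base[sym] += int(num or 1)
    if "X" not in base:
        return [base]
    out = []
    n = base.pop("X")
    for hal in HALOGENS:
        c = Counter(base)
        c[hal] += n
        out.append(c)
    return out


def _rule_possible(rule_cfg, mol_x, mol_y):
    qa = Chem.MolFromSmarts(rule_cfg["role_a"])
    qb = Chem.MolFromSmarts(rule_cfg["role_b"])
    return mol_x.HasSubstructMatch(qa) and mol_y.HasSubstructMatch(qb)


def naive_pair_products(mol_a, mol_b, rule_name, config) -> set[str]:
    """InChI products of one rule on one ordered-pair-agnostic reagent pair,
    or empty set when the pairing is vetoed."""
    rules_cfg = config["rules"]
    rule_cfg = rules_cfg[rule_name]
    possible = (_rule_possible(rule_cfg, mol_a, mol_b)
                or _rule_possible(rule_cfg, mol_b, mol_a))
    if not possible:
        return set()
    klass = rule_cfg["condition_class"]
    for side in config["side_patterns"].values():
        if klass not in side["blocks_under"]:
            continue
        q = Chem.MolFromSmarts(side["pattern"])
        if mol_a.HasSubstructMatch(q) or mol_b.HasSubstructMatch(q):
            return set()
    for other, other_cfg in rules_cfg.items():
        if other == rule_name or other_cfg["condition_class"] != klass:
            continue
        if (_rule_possible(other_cfg, mol_a, mol_b)
                or _rule_possible(other_cfg, mol_b, mol_a)):
            return set()
    rxn = AllChem.ReactionFromSmarts(rule_cfg["transform"])
    combined = _counts(mol_a) + _counts(mol_b)
    leaving = _leaving_variants(rule_cfg["leaving_formula"])
    out = set()
    for x, y in ((mol_a, mol_b), (mol_b, mol_a)):
        for prods in rxn.RunReactants((x, y)):
            for p in prods:
                try:
                    Chem.SanitizeMol(p)
                except Exception:
                    continue
                diff = combined - _counts(p)
                if not any(diff == cand for cand in leaving):
                    continue
                inchi = Chem.MolToInchi(p)
                if inchi:
                    out.add((inchi, Chem.MolToSmiles(p)))
    return out


def naive_enumerate(block_smiles: dict[str, str], config, steps: int = 2):
    """Exhaustive enumeration oracle.

    Returns ``(step1, step2)``: mappings InChI -> set of frozensets of the
    block ids that can make the product (step2 excludes step1 keys and the
    blocks themselves).
    """
    mols = {i: Chem.MolFromSmiles(s) for i, s in block_smiles.items()}
    block_inchis = {Chem.MolToInchi(m) for m in mols.values()}
    rule_names = list(config["rules"])

    step1: dict[str, dict] = {}
    ids = sorted(mols)
    for i in ids:
        for j in ids:
            for rule in rule_names:
                for inchi, smi in naive_pair_products(mols[i], mols[j], rule, config):
                    if inchi in block_inchis:
                        continue
                    entry = step1.setdefault(inchi, {"blocks": set(), "rules1": set(),
                                                     "smiles": smi})
                    entry["blocks"].add(frozenset((i, j)))
                    entry["rules1"].add(rule)
    step2: dict[str, dict] = {}
    if steps == 2:
        for inchi, entry in step1.items():
            # rebuild from the generated product SMILES, not an InChI round
            # trip, which may pick a different tautomer
            mol = Chem.MolFromSmiles(entry["smiles"])
            if mol is None:
                continue
            for j in ids:
                for rule in rule_names:
                    for p_inchi, p_smi in naive_pair_products(mol, mols[j], rule, config):
                        if p_inchi in block_inchis or p_inchi in step1:
                            continue
                        e2 = step2.setdefault(p_inchi, {"parents": set(), "rules2": set(),
                                                        "smiles": p_smi})
                        e2["parents"].add((inchi, j))
                        e2["rules2"].add(rule)
    return step1, step2


def naive_eliminate(prices: dict[str, float], products: dict[str, frozenset[str]],
                    target: int):
    """From-scratch greedy elimination oracle (no incremental index).

    ``products`` maps product key -> contributing block ids.  Returns the
    iteration list [(removed_id, score, products_remaining, budget_remaining)]
    and the retained id set.
    """
    surviving_blocks = set(prices)
    surviving_products = dict(products)
    iterations = []
    while len(surviving_blocks) > target:
        scores = {}
        for b in surviving_blocks:
            n = sum(1 for blocks in surviving_products.values() if b in blocks)
            scores[b] = n / prices[b]
        low = min((scores[b], -prices[b]) for b in surviving_blocks)
        victim = max(b for b in surviving_blocks if (scores[b], -prices[b]) == low)
        surviving_blocks.remove(victim)
        surviving_products = {k: v for k, v in surviving_products.items()
                              if victim not in v}
        budget = sum(prices[b] for b in surviving_blocks)
        iterations.append((victim, low[0], len(surviving_products), budget))
    return iterations, surviving_blocks
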