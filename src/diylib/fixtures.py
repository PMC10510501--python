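"""Deterministic synthetic catalogs with controlled reactive-group mixes.

Blocks are assembled from a fixed pool of simple ring/chain cores
decorated with requested handles (amine, carboxylic acid, alcohol, aryl
halide, electron-poor heteroaryl halide, boronic acid, terminal alkyne,
olefin, thiol).  The cores are chosen to avoid accidental side-pattern
hits unless a handle explicitly introduces one, so enumeration outcomes
are governed by the requested mix.  The same seed always yields the
identical catalog.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources

from diylib.chem_io import BuildingBlock, StructureKey, standardize

HANDLE_TYPES = ("amine", "carboxylic_acid", "alcohol", "aryl_halide",
                "heteroaryl_halide", "boronic_acid", "terminal_alkyne",
                "olefin", "thiol")

# one-slot cores; the slot kind says where the handle attaches
ARYL_CORES = [
    "c1ccc({})cc1", "Cc1ccc({})cc1", "COc1ccc({})cc1", "Cc1cccc({})c1",
    "CCc1ccc({})cc1", "c1ccc2cc({})ccc2c1", "CCc1cccc({})c1", "COc1cccc({})c1",
    "Cc1ccc({})c(C)c1", "CC(C)c1ccc({})cc1", "CCCc1ccc({})cc1",
    "COc1ccc({})c(C)c1", "Cc1cc(C)cc({})c1",
]
ALKYL_CORES = [
    "C{}", "CC{}", "CCC{}", "CC(C){}", "C1CCC({})CC1", "C1CCC({})C1",
    "c1ccccc1C{}", "c1ccccc1CC{}", "COCC{}", "CC1CCC({})CC1",
    "CCCC{}", "CC(C)C{}", "C1CCCC({})C1", "Cc1ccccc1C{}",
]
# electron-poor azine cores already carrying the halide; the slot takes a
# diversifying substituent
AZINE_CORES = [
    "Clc1ccc({})cn1", "Clc1ncc({})cn1", "Brc1ccc({})cn1", "Clc1ccc({})nc1",
    "Brc1ccc({})nc1", "Clc1cnc({})cn1",
]
# two-slot cores for bifunctional blocks
BIFUNCTIONAL_CORES = [
    ("c1cc({})ccc1{}", "aryl", "aryl"),
    ("c1cc({})ccc1C{}", "aryl", "alkyl"),
    ("C({})CC{}", "alkyl", "alkyl"),
    ("C({})CCC{}", "alkyl", "alkyl"),
    ("C1CC({})CCC1{}", "alkyl", "alkyl"),
]
DIVERSIFIERS = ["C", "CC", "OC", "C(C)C"]
INERT_SUBSTITUENTS = ["C", "CC", "OC", "CCC", "C(C)C", "CCCC"]

# handle substituents per slot kind
HANDLE_SUBSTITUENTS: dict[str, dict[str, list[str]]] = {
    "amine": {"aryl": ["N", "CN", "CCN"], "alkyl": ["N", "CN"]},
    "carboxylic_acid": {"aryl": ["C(=O)O", "CC(=O)O"], "alkyl": ["C(=O)O", "CC(=O)O"]},
    "alcohol": {"aryl": ["CO", "CCO"], "alkyl": ["O", "CO"]},
    "aryl_halide": {"aryl": ["Br", "Cl"]},
    "boronic_acid": {"aryl": ["B(O)O"], "alkyl": ["C=CB(O)O"]},  # aryl + vinyl boronics
    "terminal_alkyne": {"aryl": ["C#C"], "alkyl": ["C#C"]},
    "olefin": {"aryl": ["C=C"], "alkyl": ["C=C"]},
    "thiol": {"aryl": ["CS"], "alkyl": ["S"]},
}


@dataclass(frozen=True)
class CatalogSpec:
    """Specification of a synthetic catalog.

    ``group_mix`` maps handle types to fractions of the catalog (summing to
    at most 1; the remainder is inert).  ``bifunctional_fraction`` of the
    blocks carry a second handle.  Prices are drawn from the given
    distribution over ``[price_min, price_max]``; the defaults emulate a
    sub-10-USD-per-gram reagent catalog.
    """

    n_blocks: int
    group_mix: dict[str, float] = field(default_factory=lambda: {
        "amine": 0.25, "carboxylic_acid": 0.20, "alcohol": 0.12,
        "aryl_halide": 0.12, "heteroaryl_halide": 0.08, "boronic_acid": 0.08,
        "terminal_alkyne": 0.05, "olefin": 0.05, "thiol": 0.02,
    })
    bifunctional_fraction: float = 0.15
    price_min: float = 4.5
    price_max: float = 10.0
    price_distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        unknown = set(self.group_mix) - set(HANDLE_TYPES)
        if unknown:
            raise ValueError(f"unknown handle type(s): {sorted(unknown)}")
        total = sum(self.group_mix.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"group_mix fractions sum to {total:.3f} > 1")
        if any(f < 0 for f in self.group_mix.values()):
            raise ValueError("group_mix fractions must be nonnegative")
        if not (0.0 <= self.bifunctional_fraction <= 1.0):
            raise ValueError("bifunctional_fraction must be in [0, 1]")
        if self.price_min <= 0 or self.price_max < self.price_min:
            raise ValueError("need 0 < price_min <= price_max")
        if self.price_distribution not in ("uniform",):
            raise ValueError(f"unknown price distribution {self.price_distribution!r}")


def _allocate(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n blocks over handle types."""
    target_total = round(sum(fractions.values()) * n)
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = target_total - sum(counts.values())
    by_frac = sorted(fractions, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def _build_monofunctional(handle: str, rng: random.Random) -> str:
    if handle == "heteroaryl_halide":
        core = rng.choice(AZINE_CORES)
        return core.format(rng.choice(DIVERSIFIERS))
    slots = HANDLE_SUBSTITUENTS[handle]
    kind = rng.choice(sorted(slots))
    core = rng.choice(ARYL_CORES if kind == "aryl" else ALKYL_CORES)
    return core.format(rng.choice(slots[kind]))


def _build_bifunctional(h1: str, h2: str, rng: random.Random) -> str | None:
    if "heteroaryl_halide" in (h1, h2):
        other = h2 if h1 == "heteroaryl_halide" else h1
        slots = HANDLE_SUBSTITUENTS[other]
        if "aryl" not in slots:
            return None
        core = rng.choice(AZINE_CORES)
        return core.format(rng.choice(slots["aryl"]))
    core, kind1, kind2 = rng.choice(BIFUNCTIONAL_CORES)
    s1 = HANDLE_SUBSTITUENTS[h1].get(kind1)
    s2 = HANDLE_SUBSTITUENTS[h2].get(kind2)
    if s1 is None or s2 is None:
        return None
    return core.format(rng.choice(s1), rng.choice(s2))


def generate_catalog(spec: CatalogSpec) -> list[BuildingBlock]:
    """Generate a deterministic priced catalog realizing ``spec``.

    Exactly ``round(bifunctional_fraction * n_blocks)`` blocks carry two
    handles; handle-type counts follow largest-remainder allocation of the
    mix.  Every block parses, standardizes and is structurally unique.
    """
    rng = random.Random(spec.seed)
    counts = _allocate(spec.n_blocks, spec.group_mix)
    n_reactive = sum(counts.values())
    n_bif = round(spec.bifunctional_fraction * spec.n_blocks)
    if n_bif > n_reactive:
        raise ValueError(f"bifunctional_fraction needs {n_bif} reactive blocks "
                         f"but the mix provides only {n_reactive}")
    assignments: list[tuple[str, ...]] = []
    mix_types = sorted(k for k, v in spec.group_mix.items() if v > 0)
    primary = [h for h in sorted(counts) for _ in range(counts[h])]
    for i, h1 in enumerate(primary):
        if i < n_bif:
            h2 = rng.choice(mix_types)
            assignments.append((h1, h2))
        else:
            assignments.append((h1,))
    assignments += [()] * (spec.n_blocks - n_reactive)

    blocks: list[BuildingBlock] = []
    seen: set[str] = set()
    for idx, handles in enumerate(assignments):
        key: StructureKey | None = None
        for _attempt in range(200):
            if len(handles) == 0:
                core = rng.choice(ARYL_CORES + ALKYL_CORES)
                smi = core.format(rng.choice(INERT_SUBSTITUENTS))
            elif len(handles) == 1:
                smi = _build_monofunctional(handles[0], rng)
            else:
                smi = _build_bifunctional(handles[0], handles[1], rng)
                if smi is None:
                    handles = (handles[0], rng.choice(mix_types))
                    continue
            try:
                cand = standardize(smi)
            except Exception:
                continue
            if cand.inchi not in seen:
                key = cand
                break
        if key is None:
            raise RuntimeError(f"could not build a unique block for handles {handles}")
        seen.add(key.inchi)
        price = round(rng.uniform(spec.price_min, spec.price_max), 2)
        blocks.append(BuildingBlock(id=f"bb{idx + 1:04d}", smiles=key.canonical_smiles,
                                    price=price, source_row=idx, key=key))
    return blocks


# ---------------------------------------------------------------------------
# frozen known-answer micro-world

KNOWN_ANSWER_BLOCKS: list[tuple[str, str, float]] = [
    ("acid_acetic", "CC(=O)O", 5.0),
    ("acid_benzoic", "OC(=O)c1ccccc1", 6.0),
    ("amine_methyl", "CN", 3.0),
    ("amine_aniline", "Nc1ccccc1", 4.0),
    ("amine_ethylenediamine", "NCCN", 2.5),
    ("amine_benzyl", "NCc1ccccc1", 7.0),
    ("arx_bromobenzene", "Brc1ccccc1", 8.0),
    ("boronic_phenyl", "OB(O)c1ccccc1", 9.0),
]


def generate_known_answer_set() -> tuple[list[BuildingBlock], dict]:
    """The frozen hand-verified micro-world used as a regression anchor.

    Returns the 8-block catalog and the expected results dictionary
    (step-1/step-2 product InChI sets, per-(rule, step) counts, and the
    greedy elimination trace down to 5 blocks), as computed once by an
    independent naive enumerator and frozen into package data.
    """
    blocks = [BuildingBlock(id=i, smiles=s, price=p, source_row=n)
              for n, (i, s, p) in enumerate(KNOWN_ANSWER_BLOCKS)]
    text = resources.files("diylib.data").joinpath("known_answer.json").read_text(encoding="utf-8")
    expected = json.loads(text)
    expected["step1_inchis"] = set(expected["step1_inchis"])
    expected["step2_inchis"] = set(expected["step2_inchis"])
    expected["rule_counts"] = {
        (rule, int(step)): n
        for cell, n in expected["rule_counts"].items()
        for rule, step in [cell.rsplit("@", 1)]
    }
    return blocks, expected
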