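import sys
from pathlib import Path

import pytest
import yaml

sys.path.insert(0, str(Path(__file__).parent))

from diylib.chem_io import BuildingBlock
from diylib.enumeration import ProductLibrary, enumerate_step1, enumerate_step2
from diylib.fixtures import generate_known_answer_set
from diylib.reactions import _default_config_text, load_rule_set


@pytest.fixture(scope="session")
def rule_set():
    return load_rule_set()


@pytest.fixture(scope="session")
def config_dict():
    return yaml.safe_load(_default_config_text())


@pytest.fixture(scope="session")
def known_world():
    """The frozen 8-block micro-world plus its oracle-frozen expectations."""
    blocks, expected = generate_known_answer_set()
    return blocks, expected


@pytest.fixture(scope="session")
def known_libraries(known_world, rule_set):
    blocks, _ = known_world
    rules, sides = rule_set
    step1 = enumerate_step1(blocks, rules, sides)
    step2 = enumerate_step2(step1, blocks, rules, sides)
    return step1, step2, ProductLibrary.combined(step1, step2)


def make_blocks(spec: list[tuple[str, str, float]]) -> list[BuildingBlock]:
    return [BuildingBlock(id=i, smiles=s, price=p) for i, s, p in spec]


@pytest.fixture
def simple_acid_amine_blocks():
    """3 monofunctional acids x 4 monofunctional amines plus one biaryl
    coupling pair: 12 amides, 1 biphenyl (and 4 Buchwald arylamines) at
    step 1."""
    return make_blocks([
        ("a1", "CC(=O)O", 5.0), ("a2", "CCC(=O)O", 5.0), ("a3", "OC(=O)c1ccccc1", 6.0),
        ("n1", "CN", 3.0), ("n2", "CCN", 3.0), ("n3", "Nc1ccccc1", 4.0),
        ("n4", "NC1CCCCC1", 4.0),
        ("x1", "Brc1ccccc1", 8.0), ("b1", "OB(O)c1ccccc1", 9.0),
    ])
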