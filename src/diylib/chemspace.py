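"""Chemical-space mapping and novelty checking.

Products are described by circular (Morgan/ECFP4-style, radius 2)
fingerprints folded to a fixed length and embedded in 2-D with t-SNE
(random initialization, fixed seed, Euclidean metric on the binary
matrix).  Novelty against reference sets is byte-exact InChI membership.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.manifold import TSNE

from diylib.chem_io import StructureKey, mol_from_key

logger = logging.getLogger("diylib.chemspace")


@dataclass(frozen=True)
class FingerprintSet:
    """Binary fingerprint matrix aligned to an ordered key list."""

    keys: tuple[StructureKey, ...]
    bits: np.ndarray  # shape (n_molecules, n_bits), dtype uint8

    def __post_init__(self) -> None:
        if self.bits.shape[0] != len(self.keys):
            raise ValueError("fingerprint row count must equal key count")


@dataclass(frozen=True)
class Embedding:
    """2-D t-SNE coordinates aligned to an ordered key list."""

    keys: tuple[StructureKey, ...]
    coords: np.ndarray  # shape (n_molecules, 2)
    perplexity: float
    seed: int
    iterations: int


def fingerprint(molecules: Iterable[StructureKey | str], radius: int = 2,
                n_bits: int = 2048) -> FingerprintSet:
    """Morgan fingerprints of the given radius folded to ``n_bits``.

    Unparseable inputs are skipped with a logged warning.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    keys: list[StructureKey] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for m in molecules:
        if isinstance(m, StructureKey):
            key, mol = m, mol_from_key(m)
        else:
            mol = Chem.MolFromSmiles(m)
            if mol is None:
                skipped += 1
                continue
            key = StructureKey(inchi=Chem.MolToInchi(mol), canonical_smiles=Chem.MolToSmiles(mol))
        keys.append(key)
        rows.append(gen.GetFingerprintAsNumPy(mol).astype(np.uint8))
    if skipped:
        logger.warning("fingerprint: skipped %d unparseable molecule(s)", skipped)
    bits = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)
    return FingerprintSet(keys=tuple(keys), bits=bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two binary fingerprint rows."""
    inter = int(np.sum((a > 0) & (b > 0)))
    union = int(np.sum((a > 0) | (b > 0)))
    return inter / union if union else 1.0


def embed(fps: FingerprintSet, perplexity: float = 70.0, seed: int = 0,
          iterations: int = 1000) -> Embedding:
    """t-SNE embedding of a fingerprint set; deterministic for a fixed seed.

    The requested perplexity is reduced (with a warning) when fewer than
    ``3 * perplexity`` molecules are supplied; fewer than 5 molecules is an
    error.
    """
    n = len(fps.keys)
    if n < 5:
        raise ValueError(f"embedding needs at least 5 molecules, got {n}")
    eff_perplexity = perplexity
    if n < 3 * perplexity:
        eff_perplexity = max(5.0, (n - 1) / 3.0)
        logger.warning("perplexity %.0f too large for n=%d; reduced to %.1f",
                       perplexity, n, eff_perplexity)
    tsne = TSNE(n_components=2, perplexity=eff_perplexity, init="random",
                random_state=seed, max_iter=iterations, metric="euclidean",
                n_jobs=1)
    coords = tsne.fit_transform(fps.bits.astype(np.float32))
    return Embedding(keys=fps.keys, coords=np.asarray(coords, dtype=np.float64),
                     perplexity=eff_perplexity, seed=seed, iterations=iterations)


def sample_keys(keys: Sequence[StructureKey], n: int, seed: int) -> list[StructureKey]:
    """Seeded subsample (without replacement) for large-library embedding."""
    rng = random.Random(seed)
    keys = sorted(keys, key=lambda k: k.inchi)
    if n >= len(keys):
        return list(keys)
    return rng.sample(keys, n)


@dataclass(frozen=True)
class NoveltyResult:
    novel: tuple[StructureKey, ...]
    overlap: tuple[StructureKey, ...]
    fraction: float
    skipped_reference_lines: int = 0


def novelty_check(products: Iterable[StructureKey],
                  reference: str | Path | Iterable[str]) -> NoveltyResult:
    """Exact-match novelty of products against a reference InChI set.

    ``reference`` is a file (one InChI per line) or an iterable of InChI
    strings; malformed lines are skipped with a warning count.  The
    novelty fraction is ``|novel| / |products|``.
    """
    products = list(products)
    if not products:
        raise ValueError("novelty_check requires at least one product")
    skipped = 0
    ref: set[str] = set()
    if isinstance(reference, (str, Path)):
        lines = Path(reference).read_text(encoding="utf-8").splitlines()
    else:
        lines = list(reference)
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if not line.startswith("InChI="):
            skipped += 1
            continue
        ref.add(line)
    if skipped:
        logger.warning("novelty_check: skipped %d malformed reference line(s)", skipped)
    novel = tuple(k for k in products if k.inchi not in ref)
    overlap = tuple(k for k in products if k.inchi in ref)
    return NoveltyResult(novel=novel, overlap=overlap,
                         fraction=len(novel) / len(products),
                         skipped_reference_lines=skipped)
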