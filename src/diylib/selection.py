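"""Cost-aware building-block selection by iterative reaction-score elimination.

Each block's reaction score is the number of distinct end-products it
contributes to, divided by its price per gram.  The elimination loop
recomputes every score on the current surviving product set, removes the
single lowest-scoring block (ties: remove the higher-priced block, then
the lexicographically greatest id, so cheaper reagents are preferred),
drops every product that depended on it, and repeats until the requested
number of blocks remains.  An inverted product<->block index keeps each
iteration incremental; the incremental state is contractually identical
to a from-scratch recomputation at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from diylib.chem_io import BuildingBlock
from diylib.enumeration import ProductLibrary, ProductRecord


@dataclass(frozen=True)
class IterationRecord:
    removed_bb_id: str
    score: float
    products_remaining: int
    budget_remaining: float


@dataclass
class EliminationTrace:
    """Ordered log of the greedy elimination."""

    initial_blocks: int
    initial_products: int
    initial_budget: float
    iterations: list[IterationRecord]
    retained: frozenset[str]


def build_index(library: ProductLibrary | Iterable[ProductRecord],
                ) -> dict[str, set[str]]:
    """Inverted index block id -> set of product InChIs it contributes to."""
    index: dict[str, set[str]] = {}
    for rec in library:
        for bb_id in rec.contributing_blocks:
            index.setdefault(bb_id, set()).add(rec.key.inchi)
    return index


def reaction_score(bb_id: str, index: Mapping[str, set[str]], price: float) -> float:
    """Products contributed to, divided by price; a block appearing twice in
    one route still counts that product once."""
    if price <= 0:
        raise ValueError(f"price must be positive, got {price}")
    if bb_id not in index:
        raise KeyError(f"unknown building block id {bb_id!r}")
    return len(index[bb_id]) / price


def eliminate(blocks: Sequence[BuildingBlock], library: ProductLibrary,
              target_count: int) -> EliminationTrace:
    """Greedy lowest-score elimination down to ``target_count`` blocks."""
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if target_count > len(blocks):
        raise ValueError(f"target_count {target_count} exceeds catalog size {len(blocks)}")
    prices = {b.id: b.price for b in blocks}
    # block -> surviving products, product -> blocks (both updated in place)
    block_products: dict[str, set[str]] = {b.id: set() for b in blocks}
    for bb_id, prods in build_index(library).items():
        if bb_id not in block_products:
            raise KeyError(f"library references unknown block id {bb_id!r}")
        block_products[bb_id] = set(prods)
    product_blocks: dict[str, frozenset[str]] = {
        rec.key.inchi: rec.contributing_blocks for rec in library}

    surviving = dict.fromkeys(sorted(prices))
    n_products = len(product_blocks)
    budget = sum(prices.values())
    iterations: list[IterationRecord] = []
    trace = EliminationTrace(initial_blocks=len(surviving), initial_products=n_products,
                            initial_budget=budget, iterations=iterations,
                            retained=frozenset(surviving))
    while len(surviving) > target_count:
        # lowest score; ties -> higher price, then lexicographically greatest id
        best_key = min((len(block_products[b]) / prices[b], -prices[b]) for b in surviving)
        victim = max(b for b in surviving
                     if (len(block_products[b]) / prices[b], -prices[b]) == best_key)
        score = best_key[0]
        dead_products = block_products.pop(victim)
        for inchi in dead_products:
            for other in product_blocks[inchi]:
                if other != victim and other in block_products:
                    block_products[other].discard(inchi)
        del surviving[victim]
        n_products -= len(dead_products)
        budget -= prices[victim]
        iterations.append(IterationRecord(
            removed_bb_id=victim, score=score,
            products_remaining=n_products, budget_remaining=budget))
    trace.retained = frozenset(surviving)
    return trace


def budget_curve(trace: EliminationTrace, blocks: Sequence[BuildingBlock],
                 ) -> list[tuple[int, int, float]]:
    """(n_blocks, n_products, total_price) points, initial state first,
    ordered by descending block count - the x-axis walk of the elimination."""
    points = [(trace.initial_blocks, trace.initial_products, trace.initial_budget)]
    n = trace.initial_blocks
    for it in trace.iterations:
        n -= 1
        points.append((n, it.products_remaining, it.budget_remaining))
    return points


@dataclass(frozen=True)
class KneeResult:
    n_blocks: int
    curvature: float
    degenerate: bool


def knee_point(curve: Sequence[tuple[int, int, float]]) -> KneeResult:
    """Block count at the maximum-curvature point of products vs. budget.

    Both axes are min-max normalized; the products series is lightly
    smoothed (window 3) and discrete curvature is evaluated at interior
    points with nonuniform central differences.  A (near-)straight curve is
    degenerate: the initial point is returned with ``degenerate=True``.
    """
    if len(curve) < 5:
        raise ValueError("knee detection needs at least 5 curve points")
    pts = sorted(curve, key=lambda p: p[2])  # ascending budget
    n_blocks = np.array([p[0] for p in pts], dtype=float)
    x = np.array([p[2] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return KneeResult(n_blocks=int(max(p[0] for p in curve)), curvature=0.0, degenerate=True)
    x = (x - x.min()) / np.ptp(x)
    y = (y - y.min()) / np.ptp(y)
    # curvature from secant slopes over a window: pointwise second
    # differences would amplify sampling noise by 1/h^2
    w = max(2, len(x) // 10)
    kappa = np.zeros_like(x)
    for i in range(w, len(x) - w):
        lo, hi = i - w, i + w
        if x[i] == x[lo] or x[hi] == x[i]:
            continue
        s_left = (y[i] - y[lo]) / (x[i] - x[lo])
        s_right = (y[hi] - y[i]) / (x[hi] - x[i])
        kappa[i] = abs(np.arctan(s_right) - np.arctan(s_left))
    best = int(np.argmax(kappa))
    if kappa[best] < 1e-6:
        return KneeResult(n_blocks=int(max(p[0] for p in curve)), curvature=float(kappa[best]),
                          degenerate=True)
    return KneeResult(n_blocks=int(n_blocks[best]), curvature=float(kappa[best]), degenerate=False)
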