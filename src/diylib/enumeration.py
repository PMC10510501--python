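"""One- and two-step combinatorial library enumeration with route provenance.

Step 1 pairs catalog blocks with each other (self-pairing allowed: two
physical copies of one reagent); step 2 pairs each step-1 intermediate
with the *original* blocks only - intermediates never react with other
intermediates.  Products are deduplicated by InChI with route merging; a
molecule reachable in one step keeps its one-step route and is not
re-recorded as a two-step product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from diylib.chem_io import BuildingBlock, StructureKey
from diylib.reactions import ReactionRule, SidePattern, SiteReport, apply_rule, compatible, scan_sites

logger = logging.getLogger("diylib.enumeration")


@dataclass(frozen=True)
class Route:
    """An ordered synthetic route: per step, the rule and the blocks consumed."""

    steps: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.steps) not in (1, 2):
            raise ValueError("routes have 1 or 2 steps")
        n_ids = sum(len(ids) for _, ids in self.steps)
        if len(self.steps) == 1 and n_ids != 2:
            raise ValueError("a 1-step route references exactly 2 block ids")
        if len(self.steps) == 2 and n_ids != 3:
            raise ValueError("a 2-step route references exactly 3 block ids")

    @property
    def step_count(self) -> int:
        return len(self.steps)

    def bb_ids(self) -> tuple[str, ...]:
        return tuple(i for _, ids in self.steps for i in ids)


@dataclass
class ProductRecord:
    """An enumerated molecule with all recorded routes."""

    key: StructureKey
    routes: list[Route] = field(default_factory=list)

    @property
    def contributing_blocks(self) -> frozenset[str]:
        return frozenset(i for r in self.routes for i in r.bb_ids())

    def preferred_route(self) -> Route:
        """Fewest steps first, ties broken by route identity for determinism."""
        return min(self.routes, key=lambda r: (r.step_count, r.steps))


class ProductLibrary:
    """A set of :class:`ProductRecord` keyed by InChI."""

    def __init__(self) -> None:
        self._records: dict[str, ProductRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, inchi: str) -> bool:
        return inchi in self._records

    def __iter__(self) -> Iterator[ProductRecord]:
        return iter(self._records.values())

    def get(self, inchi: str) -> ProductRecord | None:
        return self._records.get(inchi)

    def keys(self) -> set[str]:
        return set(self._records)

    def add(self, key: StructureKey, route: Route) -> None:
        rec = self._records.get(key.inchi)
        if rec is None:
            self._records[key.inchi] = ProductRecord(key=key, routes=[route])
        elif route not in rec.routes:
            rec.routes.append(route)

    def merge(self, other: "ProductLibrary") -> None:
        for rec in other:
            for route in rec.routes:
                self.add(rec.key, route)

    def sorted_records(self) -> list[ProductRecord]:
        out = sorted(self._records.values(), key=lambda r: r.key.inchi)
        for rec in out:
            rec.routes.sort(key=lambda r: (r.step_count, r.steps))
        return out

    @staticmethod
    def combined(*libs: "ProductLibrary") -> "ProductLibrary":
        out = ProductLibrary()
        for lib in libs:
            out.merge(lib)
        return out


def _scan_blocks(blocks: Sequence[BuildingBlock], rules, side_patterns) -> dict[str, SiteReport]:
    reports: dict[str, SiteReport] = {}
    by_inchi: dict[str, SiteReport] = {}
    for b in blocks:
        if b.key.inchi not in by_inchi:
            by_inchi[b.key.inchi] = scan_sites(b.key, rules, side_patterns)
        reports[b.id] = by_inchi[b.key.inchi]
    return reports


def _partition(items: list, n_partitions: int) -> list[list]:
    n = max(1, int(n_partitions))
    return [items[i::n] for i in range(n)]


def enumerate_step1(blocks: Sequence[BuildingBlock], rules: Sequence[ReactionRule],
                    side_patterns: Sequence[SidePattern], *,
                    allow_self_pairing: bool = True, max_products_per_pair: int = 8,
                    n_partitions: int = 1) -> ProductLibrary:
    """Enumerate all one-step products over unordered block pairs.

    Every unordered pair (optionally including a block with itself) is
    tested against every rule; allowed pairs are reacted and the products
    deduplicated by InChI with route merging.  Products identical to a
    catalog block are not recorded.  ``n_partitions`` splits the pair list
    into chunks merged afterwards; the result is independent of the
    partitioning.
    """
    blocks = sorted(blocks, key=lambda b: b.id)
    reports = _scan_blocks(blocks, rules, side_patterns)
    block_inchis = {b.key.inchi for b in blocks}
    pairs = [(i, j) for i in range(len(blocks)) for j in range(i, len(blocks))
             if allow_self_pairing or i != j]
    chunks = _partition(pairs, n_partitions)
    parts: list[ProductLibrary] = []
    for chunk in chunks:
        lib = ProductLibrary()
        for i, j in chunk:
            a, b = blocks[i], blocks[j]
            ra, rb = reports[a.id], reports[b.id]
            for rule in rules:
                ok, _reason = compatible(ra, rb, rule)
                if not ok:
                    continue
                route = Route(steps=((rule.name, (a.id, b.id)),))
                for key in apply_rule(a.key, b.key, rule, max_products=max_products_per_pair):
                    if key.inchi in block_inchis:
                        continue
                    lib.add(key, route)
        parts.append(lib)
    return ProductLibrary.combined(*parts)


def enumerate_step2(step1_library: ProductLibrary, blocks: Sequence[BuildingBlock],
                    rules: Sequence[ReactionRule], side_patterns: Sequence[SidePattern], *,
                    max_products_per_pair: int = 8, n_partitions: int = 1) -> ProductLibrary:
    """Enumerate second-step products: intermediates x original blocks only.

    Returns the library of products that are *new* at step 2 - molecules
    already reachable in one step (or identical to a catalog block) are
    skipped, keeping their one-step route preferred.  Each new product's
    route is the intermediate's preferred route extended by one step.
    """
    blocks = sorted(blocks, key=lambda b: b.id)
    reports = _scan_blocks(blocks, rules, side_patterns)
    block_inchis = {b.key.inchi for b in blocks}
    step1_keys = step1_library.keys()
    intermediates = step1_library.sorted_records()
    chunks = _partition(list(range(len(intermediates))), n_partitions)
    parts: list[ProductLibrary] = []
    for chunk in chunks:
        lib = ProductLibrary()
        for idx in chunk:
            inter = intermediates[idx]
            inter_report = scan_sites(inter.key, rules, side_patterns)
            parent = inter.preferred_route()
            for b in blocks:
                rb = reports[b.id]
                for rule in rules:
                    ok, _reason = compatible(inter_report, rb, rule)
                    if not ok:
                        continue
                    route = Route(steps=parent.steps + ((rule.name, (b.id,)),))
                    for key in apply_rule(inter.key, b.key, rule,
                                          max_products=max_products_per_pair):
                        if key.inchi in block_inchis or key.inchi in step1_keys:
                            continue
                        lib.add(key, route)
        parts.append(lib)
    return ProductLibrary.combined(*parts)


def tabulate_by_rule(library: ProductLibrary | Iterable[ProductRecord],
                     ) -> tuple[dict[tuple[str, int], int], int]:
    """Per (rule, step) product counts, plus the total unique-product count.

    A product with several routes counts once in every (rule, step) cell
    it appears in; the total counts each unique molecule once.
    """
    counts: dict[tuple[str, int], int] = {}
    total = 0
    for rec in library:
        total += 1
        # a 2-step route contributes to both its step-1 and step-2 cells
        cells = {(rule, step_idx + 1) for route in rec.routes
                 for step_idx, (rule, _ids) in enumerate(route.steps)}
        for cell in cells:
            counts[cell] = counts.get(cell, 0) + 1
    return counts, total


@dataclass(frozen=True)
class RouteCost:
    """Min/max estimated cost of making a product, and the cheapest route."""

    low: float
    high: float
    cheapest_route: Route


def estimate_route_cost(product: ProductRecord, blocks: Sequence[BuildingBlock] | dict[str, BuildingBlock],
                        overhead: tuple[float, float] = (0.1, 2.5),
                        solvent_per_step: float = 1.0) -> RouteCost:
    """Estimate the direct cost range of a product over all its routes.

    Per route: sum of building-block prices, plus per reaction step a
    coupling-agent/catalyst overhead range and a flat solvent cost.  The
    reported range is the minimum/maximum over routes, and the route
    achieving the minimum is returned.
    """
    if not isinstance(blocks, dict):
        blocks = {b.id: b for b in blocks}
    lo_best, hi_best, best = None, None, None
    for route in product.routes:
        try:
            block_cost = sum(blocks[i].price for i in route.bb_ids())
        except KeyError as exc:
            raise KeyError(f"route references unknown block id {exc.args[0]!r}") from exc
        lo = block_cost + route.step_count * (overhead[0] + solvent_per_step)
        hi = block_cost + route.step_count * (overhead[1] + solvent_per_step)
        if lo_best is None or lo < lo_best:
            lo_best, best = lo, route
        if hi_best is None or hi < hi_best:
            hi_best = hi
    if best is None:
        raise ValueError("product has no routes")
    return RouteCost(low=lo_best, high=hi_best, cheapest_route=best)
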