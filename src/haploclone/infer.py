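"""Reconnection of haplotypes scattered over overlapping amplicons.

Builds a symmetric variant co-occurrence graph (edge = both variants seen on
at least one fragment), repeatedly extracts the maximum clique as a new
haplotype, recalculates and deducts the contributing fragment counts, and
continues on the remainder. Exact clique search is affordable because the
procedure is capped at 20 variants and 15 rounds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .alignment_io import AmpliconDesign
from .haplotypes import Fragment, Haplotype, HaplotypeTable
from . import _intervals
from .variants import Variant

log = logging.getLogger(__name__)

MAX_ROUNDS = 15
MAX_VARIANTS = 20


class InferenceError(ValueError):
    pass


@dataclass
class VariantGraph:
    """Co-occurrence graph over selected variants plus the fragment pool."""

    nodes: tuple[Variant, ...]
    adjacency: dict[Variant, frozenset[Variant]]
    edge_support: dict[frozenset[Variant], int]
    node_support: dict[Variant, int]
    pool: dict[frozenset[Variant], int] = field(default_factory=dict)

    def has_edge(self, a: Variant, b: Variant) -> bool:
        return b in self.adjacency.get(a, frozenset())


def _graph_from_pool(pool: dict[frozenset[Variant], int]) -> VariantGraph:
    node_support: Counter[Variant] = Counter()
    edge_support: Counter[frozenset[Variant]] = Counter()
    for key, count in pool.items():
        if count <= 0:
            continue
        for v in key:
            node_support[v] += count
        for a, b in combinations(sorted(key, key=Variant.sort_key), 2):
            edge_support[frozenset((a, b))] += count
    nodes = tuple(sorted(node_support, key=Variant.sort_key))
    adjacency: dict[Variant, set[Variant]] = {v: set() for v in nodes}
    for pair in edge_support:
        a, b = tuple(pair)
        adjacency[a].add(b)
        adjacency[b].add(a)
    return VariantGraph(
        nodes=nodes,
        adjacency={v: frozenset(s) for v, s in adjacency.items()},
        edge_support=dict(edge_support),
        node_support=dict(node_support),
        pool={k: c for k, c in pool.items() if c > 0},
    )


def build_cooccurrence_graph(
    fragments: Sequence[Fragment],
    selected: Sequence[Variant],
    max_variants: int = MAX_VARIANTS,
) -> VariantGraph:
    """Tabulate fragment key sets and build the co-occurrence graph."""
    if len(selected) > max_variants:
        raise InferenceError(
            f"{len(selected)} selected variants exceed the {max_variants}-variant cap"
        )
    sel = frozenset(selected)
    pool: Counter[frozenset[Variant]] = Counter()
    for f in fragments:
        key = f.variants & sel
        if key:
            pool[key] += 1
    return _graph_from_pool(dict(pool))


def _clique_support(graph: VariantGraph, clique: frozenset[Variant]) -> int:
    if len(clique) == 1:
        (v,) = clique
        return graph.node_support.get(v, 0)
    return sum(
        graph.edge_support.get(frozenset(p), 0) for p in combinations(clique, 2)
    )


def maximum_clique(graph: VariantGraph) -> frozenset[Variant]:
    """Exact maximum clique with deterministic tie-breaking.

    Ties between maximum-size cliques are broken by (1) larger total
    supporting fragment count, then (2) lexicographically smallest sorted
    position tuple. Bron–Kerbosch with pivoting enumerates all maximal
    cliques; n ≤ 20 keeps this cheap.
    """
    if not graph.nodes:
        return frozenset()
    best: Optional[frozenset[Variant]] = None
    best_rank: tuple = ()

    def rank(c: frozenset[Variant]) -> tuple:
        pos = tuple(sorted(v.sort_key() for v in c))
        return (len(c), _clique_support(graph, c), tuple(-p[0] for p in pos))
        # note: positions negated so "larger rank" = smaller position tuple

    def consider(c: frozenset[Variant]) -> None:
        nonlocal best, best_rank
        r = rank(c)
        if best is None or r > best_rank:
            best, best_rank = c, r

    adj = graph.adjacency
    order = {v: i for i, v in enumerate(graph.nodes)}

    def expand(r: set[Variant], p: set[Variant], x: set[Variant]) -> None:
        if not p and not x:
            consider(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: (len(adj[v] & p), -order[v]))
        for v in sorted(p - adj[pivot], key=lambda v: order[v]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(graph.nodes), set())
    assert best is not None
    return best


def _assign_amplicons(
    fragments: Sequence[Fragment], design: AmpliconDesign
) -> tuple[list[tuple[Fragment, int]], int]:
    """Assign each fragment to the amplicon its coverage overlaps most."""
    assigned: list[tuple[Fragment, int]] = []
    unassigned = 0
    for f in fragments:
        overlaps = [
            _intervals.overlap_length(f.covered, amp.segments)
            for amp in design.amplicons
        ]
        best = max(range(len(overlaps)), key=lambda i: (overlaps[i], -i))
        if overlaps[best] <= 0:
            unassigned += 1
        else:
            assigned.append((f, best))
    if unassigned:
        log.warning("%d fragments overlap no amplicon of the design", unassigned)
    return assigned, unassigned


def _restrict(clique: frozenset[Variant], design: AmpliconDesign, amp_idx: int) -> frozenset[Variant]:
    amp = design.amplicons[amp_idx]
    return frozenset(v for v in clique if amp.covers_positions(v.positions()))


def infer_scattered(
    fragments: Sequence[Fragment],
    selected: Sequence[Variant],
    design: Optional[AmpliconDesign],
    max_rounds: int = MAX_ROUNDS,
    max_variants: int = MAX_VARIANTS,
) -> HaplotypeTable:
    """Iteratively reconnect scattered haplotypes via maximum cliques.

    Each round: build the graph from the remaining pool, take the maximum
    clique C, count it as the bottleneck over C-covering amplicons of the
    remaining fragments whose key set equals C restricted to that amplicon,
    emit the row, and deduct. A round emitting 0 units, a clique of size ≤ 1,
    or the 15-round cap ends the loop; remaining pool entries are emitted as
    residual (not inferred) rows. Counts are per clone unit; the unit
    denominator is the per-amplicon fragment total divided by the number of
    amplicons, floored.
    """
    if design is None:
        raise InferenceError("inference requires an amplicon design (--amplicons)")
    if len(selected) > max_variants:
        raise InferenceError(
            f"{len(selected)} selected variants exceed the {max_variants}-variant cap"
        )
    sel = frozenset(selected)
    assigned, _ = _assign_amplicons(fragments, design)
    pool: Counter[tuple[int, frozenset[Variant]]] = Counter()
    n_assigned = 0
    for f, amp_idx in assigned:
        n_assigned += 1
        key = f.variants & sel
        if key:
            pool[(amp_idx, key)] += 1

    unit_denominator = n_assigned // len(design) if len(design) else 0
    rows: list[Haplotype] = []

    for round_no in range(1, max_rounds + 1):
        flat: Counter[frozenset[Variant]] = Counter()
        for (_, key), count in pool.items():
            if count > 0:
                flat[key] += count
        if not flat:
            break
        graph = _graph_from_pool(dict(flat))
        clique = maximum_clique(graph)
        if len(clique) <= 1:
            break
        count, contributing = _bottleneck(clique, pool, design)
        if count <= 0:
            log.info("round %d: clique %s has no consistent units left; stopping", round_no, _fmt(clique))
            break
        rows.append(
            Haplotype(
                variants=tuple(sorted(clique, key=Variant.sort_key)),
                hits=count,
                informative=unit_denominator,
                inferred=True,
            )
        )
        for entry in contributing:
            pool[entry] -= count
            if pool[entry] <= 0:
                del pool[entry]

    rows.extend(_residual_rows(pool, design, unit_denominator))
    return HaplotypeTable(
        rows=rows,
        selected=tuple(sorted(sel, key=Variant.sort_key)),
        mode="inferred",
        total_fragments=n_assigned,
        unit_denominator=unit_denominator,
    )


def _bottleneck(
    clique: frozenset[Variant],
    pool: Counter,
    design: AmpliconDesign,
) -> tuple[int, list[tuple[int, frozenset[Variant]]]]:
    """Clique unit count and the pool entries it deducts from.

    A fragment contributes to clique C only if its key set EQUALS C
    restricted to its amplicon's coverage (a fragment covering a C position
    without C's variant cannot come from clone C). The count is the minimum
    consistent remaining count over the amplicons that see any part of C.
    """
    contributing: list[tuple[int, frozenset[Variant]]] = []
    count = None
    for amp_idx in range(len(design)):
        restricted = _restrict(clique, design, amp_idx)
        if not restricted:
            continue
        entry = (amp_idx, restricted)
        available = pool.get(entry, 0)
        contributing.append(entry)
        count = available if count is None else min(count, available)
    return (count or 0), contributing


def _residual_rows(
    pool: Counter,
    design: AmpliconDesign,
    unit_denominator: int,
) -> list[Haplotype]:
    """Emit what the clique loop could not connect.

    Keys that are consistent across every amplicon covering them are counted
    as units with the same bottleneck-and-deduct rule; anything left after
    that is emitted per pool entry with a warning (the un-connectable case).
    """
    rows: list[Haplotype] = []
    keys = sorted(
        {key for (_, key), c in pool.items() if c > 0},
        key=lambda k: (-len(k), tuple(sorted(v.sort_key() for v in k))),
    )
    for key in keys:
        count, contributing = _bottleneck(key, pool, design)
        if count <= 0:
            continue
        rows.append(
            Haplotype(
                variants=tuple(sorted(key, key=Variant.sort_key)),
                hits=count,
                informative=unit_denominator,
                inferred=False,
            )
        )
        for entry in contributing:
            pool[entry] -= count
            if pool[entry] <= 0:
                del pool[entry]
    leftovers = [(amp, key, c) for (amp, key), c in pool.items() if c > 0]
    if leftovers:
        log.warning("%d pool entries could not be connected or attributed", len(leftovers))
        for amp, key, c in sorted(leftovers, key=lambda t: (t[0], tuple(sorted(v.sort_key() for v in t[1])))):
            existing = next((r for r in rows if r.key == frozenset(key) and not r.inferred), None)
            if existing is not None:
                existing.hits += c
            else:
                rows.append(
                    Haplotype(
                        variants=tuple(sorted(key, key=Variant.sort_key)),
                        hits=c,
                        informative=unit_denominator,
                        inferred=False,
                    )
                )
    return rows


def _fmt(variants: frozenset[Variant]) -> str:
    return "{" + ", ".join(f"{v.kind}@{v.start}" for v in sorted(variants, key=Variant.sort_key)) + "}"
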