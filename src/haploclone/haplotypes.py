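"""Fragment assembly (mate merging) and exact haplotype tabulation.

The fragment — a single read or a merged mate pair — is the unit of
counting; every fragment is counted exactly once.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import _intervals
from ._intervals import Intervals
from .variants import ReadObservation, Variant

log = logging.getLogger(__name__)


class PairingError(ValueError):
    pass


class CoverageIndex:
    """Vectorized "how many fragments cover these positions unmasked" counts.

    Fragments whose coverage is one contiguous interval with no masked
    positions (the overwhelmingly common case) go into numpy arrays; the
    rest fall back to exact per-fragment checks.
    """

    def __init__(self, fragments: Sequence["Fragment"]) -> None:
        import numpy as np

        starts, ends = [], []
        self._complex: list[Fragment] = []
        for f in fragments:
            if len(f.covered) == 1 and not f.masked:
                starts.append(f.covered[0][0])
                ends.append(f.covered[0][1])
            else:
                self._complex.append(f)
        self._starts = np.asarray(starts, dtype=np.int64)
        self._ends = np.asarray(ends, dtype=np.int64)

    def count_covering(self, positions: Sequence[int]) -> int:
        import numpy as np

        lo, hi = min(positions), max(positions) + 1
        n = int(np.count_nonzero((self._starts <= lo) & (self._ends >= hi)))
        for f in self._complex:
            if _intervals.contains_all(f.covered, positions) and not (
                set(positions) & f.masked
            ):
                n += 1
        return n


@dataclass(frozen=True)
class Fragment:
    """One sequencing unit: its coverage, masked positions, and variant set."""

    fragment_key: str
    covered: Intervals
    masked: frozenset[int]
    variants: frozenset[Variant]

    def covers_variant(self, v: Variant) -> bool:
        pos = v.positions()
        return _intervals.contains_all(self.covered, pos) and not (set(pos) & self.masked)

    def covers_all(self, variants: Iterable[Variant]) -> bool:
        return all(self.covers_variant(v) for v in variants)


def assemble_fragments(
    observations: Iterable[ReadObservation],
    paired: bool = True,
) -> list[Fragment]:
    """Collapse observations into one Fragment per query name.

    For mate pairs, coverage is the union of both mates. A variant present on
    one mate but contradicted by clean reference-matching coverage on the
    other mate at the same position is dropped and the position masked
    (ambiguous overlap evidence); a variant seen on both mates is kept once.
    """
    if not paired:
        return [
            Fragment(o.fragment_key, o.covered, o.masked, o.variants) for o in observations
        ]
    by_key: dict[str, list[ReadObservation]] = defaultdict(list)
    order: list[str] = []
    for o in observations:
        if o.fragment_key not in by_key:
            order.append(o.fragment_key)
        by_key[o.fragment_key].append(o)
    fragments: list[Fragment] = []
    for key in order:
        group = by_key[key]
        if len(group) > 2:
            raise PairingError(f"{len(group)} records share query name {key!r}; at most 2 allowed")
        if len(group) == 1:
            o = group[0]
            fragments.append(Fragment(key, o.covered, o.masked, o.variants))
            continue
        fragments.append(_merge_pair(key, group[0], group[1]))
    return fragments


def _merge_pair(key: str, a: ReadObservation, b: ReadObservation) -> Fragment:
    covered = _intervals.union(a.covered, b.covered)
    contradicted: set[int] = set()
    kept: set[Variant] = set()
    for v in a.variants | b.variants:
        in_a, in_b = v in a.variants, v in b.variants
        if in_a and in_b:
            kept.add(v)
            continue
        other = b if in_a else a
        pos = v.positions()
        # clean coverage on the other mate without the variant contradicts it
        if (
            _intervals.contains_all(other.covered, pos)
            and not (set(pos) & other.masked)
        ):
            contradicted.update(pos)
        else:
            kept.add(v)  # e.g. the other mate had an N there: clear call wins
    # a contradicted position may also knock out a variant kept above
    # (two disagreeing calls at one position contradict each other)
    kept = {v for v in kept if not (set(v.positions()) & contradicted)}
    masked = (set(a.masked) | set(b.masked) | contradicted) - {
        p for v in kept for p in v.positions()
    }
    return Fragment(key, covered, frozenset(masked), frozenset(kept))


@dataclass(frozen=True)
class VariantSummary:
    variant: Variant
    supporting: int
    covering: int

    @property
    def frequency(self) -> float:
        return self.supporting / self.covering if self.covering else 0.0


def detect_variant_table(fragments: Sequence[Fragment]) -> list[VariantSummary]:
    """Per-variant support and coverage over all fragments (frequency =
    supporting / covering); sorted by reference position."""
    support: Counter[Variant] = Counter()
    for f in fragments:
        support.update(f.variants)
    index = CoverageIndex(fragments)
    rows = []
    for v in sorted(support, key=Variant.sort_key):
        covering = index.count_covering(v.positions())
        rows.append(VariantSummary(variant=v, supporting=support[v], covering=covering))
    return rows


@dataclass
class Haplotype:
    """One output row: a variant combination with its counts."""

    variants: tuple[Variant, ...]  # sorted, non-empty
    hits: int
    informative: int = 0
    percentage: Optional[float] = None
    inferred: bool = False

    @property
    def key(self) -> frozenset[Variant]:
        return frozenset(self.variants)


@dataclass
class HaplotypeTable:
    rows: list[Haplotype]
    selected: tuple[Variant, ...]
    mode: str  # "default" | "inferred"
    total_fragments: int
    variant_coverage: dict[Variant, int] = field(default_factory=dict)
    wildtype_percentage: Optional[float] = None
    n_empty_key: int = 0  # fragments covering ≥1 selected position, no variant
    n_uninformative: int = 0  # fragments covering no selected position
    unit_denominator: Optional[int] = None  # inferred mode only

    def row_for(self, variants: Iterable[Variant]) -> Optional[Haplotype]:
        key = frozenset(variants)
        for row in self.rows:
            if row.key == key:
                return row
        return None


def tabulate(
    fragments: Sequence[Fragment],
    selected: Optional[Sequence[Variant]] = None,
) -> HaplotypeTable:
    """Group fragments by their selected-variant key sets, exactly.

    Each fragment's key is its variant set intersected with the selection
    (its variants are, by construction, observed at covered unmasked
    positions). Non-empty keys become rows; ``hits`` is the group size and
    ``informative`` the number of fragments covering ALL of the row's
    variant positions unmasked. Fragments with empty keys contribute to no
    row; they enter the wild-type estimate only through the percentage
    complement.
    """
    if selected is None or len(selected) == 0:
        detected: set[Variant] = set()
        for f in fragments:
            detected |= f.variants
        selected = sorted(detected, key=Variant.sort_key)
    sel_set = frozenset(selected)
    groups: Counter[frozenset[Variant]] = Counter()
    n_empty = 0
    n_uninf = 0
    for f in fragments:
        key = f.variants & sel_set
        if key:
            groups[key] += 1
        elif any(f.covers_variant(v) for v in sel_set):
            n_empty += 1
        else:
            n_uninf += 1
    index = CoverageIndex(fragments)
    coverage = {v: index.count_covering(v.positions()) for v in sel_set}
    rows = []
    for key in sorted(groups, key=lambda k: tuple(sorted(v.sort_key() for v in k))):
        variants = tuple(sorted(key, key=Variant.sort_key))
        informative = index.count_covering([p for v in variants for p in v.positions()])
        rows.append(Haplotype(variants=variants, hits=groups[key], informative=informative))
    return HaplotypeTable(
        rows=rows,
        selected=tuple(sorted(sel_set, key=Variant.sort_key)),
        mode="default",
        total_fragments=len(fragments),
        variant_coverage=coverage,
        n_empty_key=n_empty,
        n_uninformative=n_uninf,
    )
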