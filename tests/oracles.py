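"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths it verifies: the variant
caller is checked against a padded-matrix column comparison, indel
normalization against placement enumeration, the clique search against
subset enumeration, and amplicon inference against exhaustive enumeration of
unit mixtures.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

from haploclone.alignment_io import AmpliconDesign, ReadAlignment, Reference
from haploclone.variants import Variant


def padded_matrix_call(
    read: ReadAlignment, reference: Reference
) -> tuple[set[int], set[int], set[Variant]]:
    """Reconstruct the padded alignment matrix and compare column by column.

    Returns (covered reference positions, masked positions, variants).
    """
    cols: list[tuple[int | None, str, str]] = []  # (refpos, refchar, qchar)
    r, q = read.ref_start, 0
    for op, n in read.operations:
        if op == "S":
            q += n
        elif op == "P":
            continue
        elif op == "M":
            for _ in range(n):
                cols.append((r, reference.sequence[r], read.query_sequence[q]))
                r += 1
                q += 1
        elif op == "I":
            for _ in range(n):
                cols.append((None, "-", read.query_sequence[q]))
                q += 1
        elif op == "D":
            for _ in range(n):
                cols.append((r, reference.sequence[r], "-"))
                r += 1

    covered = {rp for rp, _, _ in cols if rp is not None}
    masked: set[int] = set()
    variants: set[Variant] = set()

    # SNVs and masks from aligned columns
    for rp, rc, qc in cols:
        if rp is None or qc == "-":
            continue
        if qc == "N" or rc == "N":
            if qc != rc:
                masked.add(rp)
        elif qc != rc:
            variants.add(Variant(start=rp, kind="SNV", ref_allele=rc, alt_allele=qc))

    # deletions: maximal runs of query gaps
    i = 0
    while i < len(cols):
        rp, rc, qc = cols[i]
        if rp is not None and qc == "-":
            j = i
            refs = []
            while j < len(cols) and cols[j][0] is not None and cols[j][2] == "-":
                refs.append(cols[j][1])
                j += 1
            variants.add(Variant(start=cols[i][0], kind="DEL", ref_allele="".join(refs), alt_allele=""))
            i = j
        else:
            i += 1

    # insertions: maximal runs of reference gaps, anchored at the next ref pos
    i = 0
    while i < len(cols):
        if cols[i][0] is None:
            j = i
            alt = []
            while j < len(cols) and cols[j][0] is None:
                alt.append(cols[j][2])
                j += 1
            nxt = cols[j][0] if j < len(cols) else None
            seq = "".join(alt)
            if nxt is not None and "N" not in seq and nxt - 1 in covered and nxt > 0:
                variants.add(Variant(start=nxt, kind="INS", ref_allele="", alt_allele=seq))
            i = j
        else:
            i += 1
    return covered, masked, variants


def apply_variant(sequence: str, v: Variant) -> str:
    if v.kind == "SNV":
        return sequence[: v.start] + v.alt_allele + sequence[v.start + 1 :]
    if v.kind == "DEL":
        return sequence[: v.start] + sequence[v.start + len(v.ref_allele) :]
    return sequence[: v.start] + v.alt_allele + sequence[v.start :]


def leftmost_equivalent(v: Variant, reference: Reference) -> Variant:
    """Enumerate every placement producing the same mutated sequence and
    return the one with the smallest start."""
    if v.kind == "SNV":
        return v
    target = apply_variant(reference.sequence, v)
    n = len(v.ref_allele) if v.kind == "DEL" else len(v.alt_allele)
    best = None
    limit = len(reference.sequence) - (n if v.kind == "DEL" else 0)
    for start in range(0, v.start + 1):
        if v.kind == "DEL":
            cand = Variant(start=start, kind="DEL",
                           ref_allele=reference.sequence[start : start + n], alt_allele="")
            if apply_variant(reference.sequence, cand) == target:
                best = cand
                break
        else:
            # any inserted sequence of length n at this junction
            inserted = target[start : start + n]
            cand = Variant(start=start, kind="INS", ref_allele="", alt_allele=inserted)
            if apply_variant(reference.sequence, cand) == target:
                best = cand
                break
    assert best is not None and limit >= 0
    return best


def brute_max_clique_size(nodes: Sequence, edges: set[frozenset]) -> int:
    """Exhaustive subset enumeration, largest size first."""
    for k in range(len(nodes), 1, -1):
        for combo in combinations(nodes, k):
            if all(frozenset(p) in edges for p in combinations(combo, 2)):
                return k
    return 1 if nodes else 0


def recount_variant_summary(fragments) -> dict[Variant, tuple[int, int]]:
    """Brute-force (supporting, covering) recount per variant."""
    out: dict[Variant, tuple[int, int]] = {}
    variants = {v for f in fragments for v in f.variants}
    for v in variants:
        pos = set(v.positions())
        supporting = sum(1 for f in fragments if v in f.variants)
        covering = 0
        for f in fragments:
            covered_positions = {p for s, e in f.covered for p in range(s, e)}
            if pos <= covered_positions and not (pos & f.masked):
                covering += 1
        out[v] = (supporting, covering)
    return out


def enumerate_unit_mixtures(
    observed: dict[tuple[int, frozenset[Variant]], int],
    design: AmpliconDesign,
    variants: Sequence[Variant],
    total_units: int,
) -> list[dict[frozenset[Variant], int]]:
    """All assignments of non-negative clone-unit counts (one count per
    subset of ``variants``, wild type included) whose per-amplicon restricted
    key-set counts reproduce ``observed`` exactly."""
    subsets = []
    for k in range(len(variants) + 1):
        for combo in combinations(variants, k):
            subsets.append(frozenset(combo))

    def restrict(subset: frozenset[Variant], amp_idx: int) -> frozenset[Variant]:
        amp = design.amplicons[amp_idx]
        return frozenset(v for v in subset if amp.covers_positions(v.positions()))

    solutions = []

    def recurse(i: int, remaining: int, counts: dict) -> None:
        if i == len(subsets):
            if remaining != 0:
                return
            predicted: dict[tuple[int, frozenset[Variant]], int] = {}
            for subset, units in counts.items():
                if units == 0:
                    continue
                for amp_idx in range(len(design)):
                    key = restrict(subset, amp_idx)
                    predicted[(amp_idx, key)] = predicted.get((amp_idx, key), 0) + units
            if predicted == observed:
                solutions.append({s: c for s, c in counts.items() if c})
            return
        for units in range(remaining + 1):
            counts[subsets[i]] = units
            recurse(i + 1, remaining - units, counts)
        del counts[subsets[i]]

    recurse(0, total_units, {})
    return solutions


def covered_position_set(fragment) -> set[int]:
    return {p for s, e in fragment.covered for p in range(s, e)}
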