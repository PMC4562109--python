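"""Mixed-clone amplicon read simulator with exact ground truth.

Generates pre-aligned reads (true operations and start positions are known,
no aligner involved) for mixtures of clones over a reference, a tiling
amplicon design, or random read windows, with a tunable substitution and
homopolymer-style indel error profile. Deterministic for a given seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .alignment_io import Amplicon, AmpliconDesign, ReadAlignment, Reference
from . import _intervals
from .variants import Variant, normalize_variant, variant_label

_BASES = "ACGT"
_CIGAR_CODES = {"M": 0, "I": 1, "D": 2, "S": 4, "P": 6}


@dataclass(frozen=True)
class CloneTruth:
    """One simulated clone: its variant set (empty = wild type) and fraction."""

    name: str
    variants: frozenset[Variant]
    proportion: float


@dataclass
class SimConfig:
    seed: int
    n_fragments: int = 1000
    reference: Optional[Reference] = None
    reference_length: int = 924
    design: Optional[AmpliconDesign] = None
    read_length: Optional[int] = None  # None = cover the whole window
    substitution_rate: float = 0.01
    indel_rate: float = 0.002
    multinomial: bool = False

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if not (0 <= self.substitution_rate < 1) or not (0 <= self.indel_rate < 1):
            raise ValueError("error rates must lie in [0, 1)")


@dataclass
class SimResult:
    reference: Reference
    reads: list[ReadAlignment]
    truth: list[CloneTruth]
    allocations: dict[str, int]  # clone name -> fragment (unit) count
    fragments_per_unit: int = 1


def random_reference(length: int, rng: np.random.Generator, name: str = "ref") -> Reference:
    seq = "".join(rng.choice(list(_BASES), size=length))
    return Reference(name=name, sequence=seq)


def make_snv(reference: Reference, pos: int, alt: Optional[str] = None) -> Variant:
    ref = reference.sequence[pos]
    if alt is None:
        alt = _BASES[(_BASES.index(ref) + 1) % 4] if ref in _BASES else "A"
    return Variant(start=pos, kind="SNV", ref_allele=ref, alt_allele=alt)


def make_deletion(reference: Reference, pos: int, length: int) -> Variant:
    v = Variant(start=pos, kind="DEL", ref_allele=reference.sequence[pos : pos + length], alt_allele="")
    return normalize_variant(v, reference)


def make_insertion(reference: Reference, pos: int, length: int) -> Variant:
    alt = "".join(_BASES[(pos + 1 + i) % 4] for i in range(length))
    v = Variant(start=pos, kind="INS", ref_allele="", alt_allele=alt)
    return normalize_variant(v, reference)


def largest_remainder_allocation(proportions: Sequence[float], total: int) -> list[int]:
    """Integer allocation that is exact in sum and deterministic."""
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_mixture(truth: Sequence[CloneTruth], config: SimConfig) -> SimResult:
    """Generate one mixed sample.

    With an amplicon design, ``n_fragments`` counts clone UNITS and every
    unit emits one fragment per amplicon (a two-segment amplicon produces a
    mate pair). Without a design, each fragment is a single read placed
    uniformly (or covering the whole reference when ``read_length`` is None).
    """
    total_p = sum(c.proportion for c in truth)
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"clone proportions sum to {total_p}, expected 1")
    rng = np.random.default_rng(config.seed)
    reference = config.reference or random_reference(config.reference_length, rng)

    region = config.design.region() if config.design else ((0, len(reference)),)
    for clone in truth:
        for v in clone.variants:
            if not _intervals.contains_all(region, v.positions()):
                raise ValueError(
                    f"clone {clone.name!r} variant at {v.start} outside the simulated region"
                )

    if config.multinomial:
        counts = list(rng.multinomial(config.n_fragments, [c.proportion for c in truth]))
    else:
        counts = largest_remainder_allocation([c.proportion for c in truth], config.n_fragments)
    allocations = {c.name: int(n) for c, n in zip(truth, counts)}

    if config.design is not None:
        amplicons = config.design.amplicons
    elif config.read_length is None or config.read_length >= len(reference):
        amplicons = (Amplicon(label="full", segments=((0, len(reference)),)),)
    else:
        amplicons = None  # random windows

    reads: list[ReadAlignment] = []
    template_cache: dict[tuple, tuple[str, tuple]] = {}
    for clone, n_units in zip(truth, counts):
        for unit in range(int(n_units)):
            if amplicons is not None:
                for amp in amplicons:
                    qname = f"{clone.name}.u{unit}.{amp.label}"
                    reads.extend(
                        _emit_fragment(qname, clone, amp.segments, reference, config, rng, template_cache)
                    )
            else:
                start = int(rng.integers(0, len(reference) - config.read_length + 1))
                qname = f"{clone.name}.u{unit}"
                reads.extend(
                    _emit_fragment(
                        qname, clone, ((start, start + config.read_length),),
                        reference, config, rng, template_cache,
                    )
                )
    return SimResult(
        reference=reference,
        reads=reads,
        truth=list(truth),
        allocations=allocations,
        fragments_per_unit=len(amplicons) if amplicons is not None else 1,
    )


def _emit_fragment(
    qname: str,
    clone: CloneTruth,
    segments: tuple[tuple[int, int], ...],
    reference: Reference,
    config: SimConfig,
    rng: np.random.Generator,
    cache: dict,
) -> list[ReadAlignment]:
    paired = len(segments) == 2
    out = []
    for i, (s, e) in enumerate(segments):
        key = (clone.name, s, e)
        if key not in cache:
            cache[key] = _apply_clone_variants(reference.sequence, s, e, clone.variants)
        query, ops = cache[key]
        query, ops = _apply_errors(query, ops, config, rng)
        if paired:
            flags = 0x1 | 0x2 | (0x40 if i == 0 else 0x80)
            mate = i + 1
        else:
            flags = 0
            mate = 0
        out.append(
            ReadAlignment(
                query_name=qname,
                mate_index=mate,
                ref_start=s,
                operations=ops,
                query_sequence=query,
                flags=flags,
            )
        )
    return out


def _apply_clone_variants(
    ref_seq: str, start: int, end: int, variants: frozenset[Variant]
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Build the error-free read for one window of one clone."""
    snv_at: dict[int, Variant] = {}
    del_at: dict[int, Variant] = {}
    ins_at: dict[int, Variant] = {}
    for v in variants:
        pos = v.positions()
        if pos[0] < start or pos[-1] >= end:
            continue  # variant outside this window: the fragment doesn't see it
        if v.kind == "SNV":
            snv_at[v.start] = v
        elif v.kind == "DEL":
            del_at[v.start] = v
        else:
            ins_at[v.start] = v
    parts: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    i = start
    while i < end:
        if i in ins_at and i > start:
            alt = ins_at[i].alt_allele
            parts.append(alt)
            push("I", len(alt))
        if i in del_at:
            n = len(del_at[i].ref_allele)
            push("D", n)
            i += n
            continue
        parts.append(snv_at[i].alt_allele if i in snv_at else ref_seq[i])
        push("M", 1)
        i += 1
    return "".join(parts), tuple(ops)


def _apply_errors(
    query: str,
    ops: tuple[tuple[str, int], ...],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, tuple[tuple[str, int], ...]]:
    n = len(query)
    if config.substitution_rate > 0:
        k = rng.binomial(n, config.substitution_rate)
        if k:
            positions = rng.choice(n, size=k, replace=False)
            chars = np.frombuffer(query.encode(), dtype=np.uint8).copy()
            for p in positions:
                current = chr(chars[p])
                options = [b for b in _BASES if b != current]
                chars[p] = ord(options[int(rng.integers(0, len(options)))])
            query = chars.tobytes().decode()
    if config.indel_rate > 0:
        k = rng.binomial(n, config.indel_rate)
        if k:
            query, ops = _apply_indel_errors(query, ops, k, rng)
    return query, ops


def _apply_indel_errors(
    query: str,
    ops: tuple[tuple[str, int], ...],
    n_events: int,
    rng: np.random.Generator,
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Inject 1-bp indel errors (insertions duplicate the local base)."""
    # expand to per-base tokens: (base, op); deletions are ('', 'D') tokens
    tokens: list[tuple[str, str]] = []
    qi = 0
    for op, length in ops:
        if op == "D":
            tokens.extend(("", "D") for _ in range(length))
        elif op == "P":
            tokens.append(("", "P"))
        else:
            for _ in range(length):
                tokens.append((query[qi], op))
                qi += 1
    for _ in range(n_events):
        q_positions = [i for i, (b, op) in enumerate(tokens) if op == "M"]
        if len(q_positions) < 3:
            break
        idx = q_positions[int(rng.integers(1, len(q_positions) - 1))]
        if rng.integers(0, 2) == 0:
            tokens.insert(idx + 1, (tokens[idx][0], "I"))  # homopolymer lengthening
        else:
            tokens[idx] = ("", "D")
    new_query = "".join(b for b, op in tokens if op in ("M", "I", "S"))
    new_ops: list[tuple[str, int]] = []
    for b, op in tokens:
        if op == "P":
            continue
        if new_ops and new_ops[-1][0] == op:
            new_ops[-1] = (op, new_ops[-1][1] + 1)
        else:
            new_ops.append((op, 1))
    return new_query, tuple(new_ops)


def to_padded_dialect(read: ReadAlignment) -> ReadAlignment:
    """Express the same alignment with an explicit pad operation.

    The first match block of length ≥ 2 is split around a 1-base pad; pads
    consume neither query nor reference, so the parsed coordinates are
    identical to the unpadded form.
    """
    ops = list(read.operations)
    for i, (op, n) in enumerate(ops):
        if op == "M" and n >= 2:
            half = n // 2
            ops[i : i + 1] = [("M", half), ("P", 1), ("M", n - half)]
            break
    return ReadAlignment(
        query_name=read.query_name,
        mate_index=read.mate_index,
        ref_start=read.ref_start,
        operations=tuple(ops),
        query_sequence=read.query_sequence,
        flags=read.flags,
    )


def write_alignment(
    reads: Sequence[ReadAlignment],
    path: str | os.PathLike,
    reference: Reference,
    padded: bool = False,
) -> None:
    """Write reads as a valid SAM file with header; byte-deterministic."""
    if padded:
        reads = [to_padded_dialect(r) for r in reads]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": reference.name, "LN": len(reference)}],
        }
    )
    mate_start: dict[tuple[str, int], int] = {}
    for r in reads:
        if r.mate_index:
            mate_start[(r.query_name, r.mate_index)] = r.ref_start
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.query_name
            seg.flag = r.flags
            seg.reference_id = 0
            seg.reference_start = r.ref_start
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_CODES[op], n) for op, n in r.operations]
            seg.query_sequence = r.query_sequence
            if r.mate_index:
                other = mate_start.get((r.query_name, 3 - r.mate_index))
                if other is not None:
                    seg.next_reference_id = 0
                    seg.next_reference_start = other
            out.write(seg)


def write_reference(reference: Reference, path: str | os.PathLike) -> None:
    with open(str(path), "w") as fh:
        fh.write(f">{reference.name}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_truth_table(result: SimResult, path: str | os.PathLike) -> None:
    """Tab-separated ground truth: clone, variant labels, proportion, units."""
    with open(str(path), "w") as fh:
        fh.write("clone\tvariants\tproportion\tunits\n")
        for clone in result.truth:
            labels = ",".join(
                variant_label(v) for v in sorted(clone.variants, key=Variant.sort_key)
            )
            fh.write(
                f"{clone.name}\t{labels or 'wt'}\t{clone.proportion:.6f}\t{result.allocations[clone.name]}\n"
            )


def write_selection(truth: Sequence[CloneTruth], path: str | os.PathLike) -> None:
    """All clone variants as a selection list (g. labels, one per line)."""
    variants = sorted({v for c in truth for v in c.variants}, key=Variant.sort_key)
    with open(str(path), "w") as fh:
        fh.write("# simulated clone variants\n")
        for v in variants:
            fh.write(variant_label(v) + "\n")


def load_sim_config(path: str | os.PathLike) -> tuple[list[CloneTruth], SimConfig, list[str]]:
    """Read a key-value simulation config.

    Recognized keys: seed, n_fragments, reference_length, read_length,
    substitution_rate, indel_rate, multinomial, and repeated
    ``clone = NAME PROPORTION [spec,spec,...]`` lines with specs
    ``snv:POS``, ``del:POS:LEN``, ``ins:POS:LEN`` (0-based positions).
    Returns (clone specs unresolved, config, raw clone spec strings); call
    :func:`resolve_clones` once the reference exists.
    """
    kv: dict[str, str] = {}
    clone_lines: list[str] = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "clone":
                clone_lines.append(value)
            else:
                kv[key] = value
    if "seed" not in kv:
        raise ValueError("config must set seed")
    config = SimConfig(
        seed=int(kv["seed"]),
        n_fragments=int(kv.get("n_fragments", 1000)),
        reference_length=int(kv.get("reference_length", 924)),
        read_length=int(kv["read_length"]) if "read_length" in kv else None,
        substitution_rate=float(kv.get("substitution_rate", 0.01)),
        indel_rate=float(kv.get("indel_rate", 0.002)),
        multinomial=kv.get("multinomial", "false").lower() in ("1", "true", "yes"),
    )
    if not clone_lines:
        raise ValueError("config must define at least one clone")
    return [], config, clone_lines


def resolve_clones(clone_lines: Sequence[str], reference: Reference) -> list[CloneTruth]:
    clones: list[CloneTruth] = []
    for line in clone_lines:
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"bad clone spec {line!r}")
        name, proportion = parts[0], float(parts[1])
        variants: set[Variant] = set()
        if len(parts) > 2:
            for spec in parts[2].split(","):
                fields = spec.split(":")
                if fields[0] == "snv":
                    variants.add(make_snv(reference, int(fields[1])))
                elif fields[0] == "del":
                    variants.add(make_deletion(reference, int(fields[1]), int(fields[2])))
                elif fields[0] == "ins":
                    variants.add(make_insertion(reference, int(fields[1]), int(fields[2])))
                else:
                    raise ValueError(f"unknown variant spec {spec!r}")
        clones.append(CloneTruth(name=name, variants=frozenset(variants), proportion=proportion))
    return clones
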