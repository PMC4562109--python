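"""Atomic variant extraction from read alignments, normalization, labels.

Haplotype identity always uses atomic variants; combined (consecutive /
same-codon) forms exist for reporting only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _intervals
from .alignment_io import GeneModel, ReadAlignment, Reference
from ._intervals import Intervals

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon, "X")


@dataclass(frozen=True, order=True)
class Variant:
    """One atomic sequence change on the reference.

    ``start`` is the 0-based reference position; for an insertion it is the
    position of the reference base immediately AFTER the insertion point
    (the inserted sequence sits between start-1 and start).
    """

    start: int
    kind: str  # "SNV" | "INS" | "DEL"
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1 or self.ref_allele == self.alt_allele:
                raise ValueError(f"bad SNV alleles {self.ref_allele!r}>{self.alt_allele!r}")
        elif self.kind == "DEL":
            if not self.ref_allele or self.alt_allele:
                raise ValueError("DEL needs non-empty ref and empty alt")
        elif self.kind == "INS":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("INS needs empty ref and non-empty alt")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    def positions(self) -> tuple[int, ...]:
        """Reference positions a fragment must cover to observe this variant."""
        if self.kind == "SNV":
            return (self.start,)
        if self.kind == "DEL":
            return tuple(range(self.start, self.start + len(self.ref_allele)))
        # INS: both flanks of the junction
        return (max(0, self.start - 1), self.start)

    def sort_key(self) -> tuple:
        return (self.start, self.kind, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ReadObservation:
    """Variants and coverage observed on a single read (one SAM record)."""

    fragment_key: str
    mate_index: int
    covered: Intervals
    masked: frozenset[int]
    variants: frozenset[Variant]

    def covers_variant(self, v: Variant) -> bool:
        pos = v.positions()
        return _intervals.contains_all(self.covered, pos) and not (set(pos) & self.masked)


def call_read_variants(read: ReadAlignment, reference: Reference) -> ReadObservation:
    """Walk the alignment operations and extract atomic variants.

    Mismatching aligned bases become SNVs, insertion/deletion operations
    become INS/DEL variants. Soft-clipped bases contribute nothing; an N in
    the read at an aligned position masks that position instead of producing
    a variant. Insertions not flanked by aligned bases on both sides are not
    called (the read does not span the junction).
    """
    ref_seq = reference.sequence
    r = read.ref_start
    q = 0
    qseq = read.query_sequence
    covered_spans: list[tuple[int, int]] = []
    masked: set[int] = set()
    variants: set[Variant] = set()
    pending_ins: list[Variant] = []
    for op, n in read.operations:
        if op == "S":
            q += n
        elif op == "P":
            continue
        elif op == "M":
            block_q = qseq[q : q + n]
            block_r = ref_seq[r : r + n]
            if block_q != block_r:
                if n > 64:
                    qa = np.frombuffer(block_q.encode(), dtype=np.uint8)
                    ra = np.frombuffer(block_r.encode(), dtype=np.uint8)
                    idx = np.nonzero(qa != ra)[0]
                else:
                    idx = [i for i in range(n) if block_q[i] != block_r[i]]
                for i in idx:
                    qb, rb = block_q[i], block_r[i]
                    if qb == "N" or rb == "N":
                        masked.add(r + int(i))
                    else:
                        variants.add(Variant(start=r + int(i), kind="SNV", ref_allele=rb, alt_allele=qb))
            covered_spans.append((r, r + n))
            r += n
            q += n
        elif op == "I":
            alt = qseq[q : q + n]
            if "N" not in alt:
                pending_ins.append(Variant(start=r, kind="INS", ref_allele="", alt_allele=alt))
            q += n
        elif op == "D":
            variants.add(Variant(start=r, kind="DEL", ref_allele=ref_seq[r : r + n], alt_allele=""))
            covered_spans.append((r, r + n))  # spanning read observes the deletion
            r += n
        else:  # pragma: no cover - parse layer guarantees the alphabet
            raise ValueError(f"unexpected operation {op!r}")
    covered = _intervals.merge(covered_spans)
    for v in pending_ins:
        # keep only junction-spanning insertions
        if v.start > 0 and _intervals.contains(covered, v.start - 1) and _intervals.contains(covered, v.start):
            variants.add(v)
    return ReadObservation(
        fragment_key=read.query_name,
        mate_index=read.mate_index,
        covered=covered,
        masked=frozenset(masked),
        variants=frozenset(variants),
    )


def normalize_variant(v: Variant, reference: Reference) -> Variant:
    """Left-align an indel to its leftmost equivalent placement."""
    ref = reference.sequence
    if v.kind == "DEL":
        start, n = v.start, len(v.ref_allele)
        while start > 0 and ref[start - 1] == ref[start + n - 1]:
            start -= 1
        if start == v.start:
            return v
        return Variant(start=start, kind="DEL", ref_allele=ref[start : start + n], alt_allele="")
    if v.kind == "INS":
        start, alt = v.start, v.alt_allele
        while start > 0 and alt[-1] == ref[start - 1]:
            alt = ref[start - 1] + alt[:-1]
            start -= 1
        if start == v.start:
            return v
        return Variant(start=start, kind="INS", ref_allele="", alt_allele=alt)
    return v


def normalize_indels(observation: ReadObservation, reference: Reference) -> ReadObservation:
    """Left-align every indel in the observation; idempotent.

    Shifting may move a variant left of the read's aligned span; the covered
    intervals are extended over the shift range so the observation invariant
    (variant positions ⊆ covered) holds for the canonical placement.
    """
    new_vars: set[Variant] = set()
    extra_spans: list[tuple[int, int]] = []
    changed = False
    for v in observation.variants:
        nv = normalize_variant(v, reference)
        if nv is not v:
            changed = True
            extra_spans.append((nv.start, v.start + max(1, len(v.ref_allele))))
        new_vars.add(nv)
    if not changed:
        return observation
    covered = _intervals.union(observation.covered, extra_spans)
    return replace(observation, covered=covered, variants=frozenset(new_vars))


@dataclass(frozen=True)
class CombinedVariant:
    """Reporting-only grouping of atomic SNVs (consecutive or same codon)."""

    members: tuple[Variant, ...]
    reason: str  # "consecutive" | "same_codon" | "single"

    def combined_label(self, model: Optional[GeneModel] = None) -> str:
        if len(self.members) == 1:
            return variant_label(self.members[0], model)
        if self.reason == "consecutive":
            first, last = self.members[0], self.members[-1]
            refs = "".join(m.ref_allele for m in self.members)
            alts = "".join(m.alt_allele for m in self.members)
            if model is not None:
                c1, c2 = model.ref_to_cds(first.start), model.ref_to_cds(last.start)
                if c1 is not None and c2 is not None:
                    lo, hi = sorted((c1, c2))
                    return f"c.{lo}_{hi}{refs}>{alts}"
            return f"g.{first.start + 1}_{last.start + 1}{refs}>{alts}"
        return "+".join(variant_label(m, model) for m in self.members)


def combine_variants(
    variants: Iterable[Variant] | ReadObservation,
    model: Optional[GeneModel] = None,
) -> list[CombinedVariant]:
    """Group SNVs that are reference-adjacent or share a codon.

    Maximal runs of adjacent SNVs combine first; remaining SNVs sharing a
    codon (needs a GeneModel) combine second; everything else passes through
    as singletons. Indels are never combined.
    """
    if isinstance(variants, ReadObservation):
        variants = variants.variants
    vs = sorted(variants, key=Variant.sort_key)
    snvs = [v for v in vs if v.kind == "SNV"]
    others = [v for v in vs if v.kind != "SNV"]
    out: list[CombinedVariant] = []
    runs: list[list[Variant]] = []
    for v in snvs:
        if runs and v.start == runs[-1][-1].start + 1:
            runs[-1].append(v)
        else:
            runs.append([v])
    leftovers: list[Variant] = []
    for run in runs:
        if len(run) > 1:
            out.append(CombinedVariant(members=tuple(run), reason="consecutive"))
        else:
            leftovers.append(run[0])
    if model is not None:
        by_codon: dict[int, list[Variant]] = {}
        no_codon: list[Variant] = []
        for v in leftovers:
            c = model.ref_to_cds(v.start)
            if c is None:
                no_codon.append(v)
            else:
                by_codon.setdefault(model.codon_of(c), []).append(v)
        leftovers = no_codon
        for codon in sorted(by_codon):
            group = by_codon[codon]
            if len(group) > 1:
                out.append(CombinedVariant(members=tuple(group), reason="same_codon"))
            else:
                leftovers.append(group[0])
    for v in sorted(leftovers, key=Variant.sort_key) + others:
        out.append(CombinedVariant(members=(v,), reason="single"))
    out.sort(key=lambda cv: cv.members[0].sort_key())
    return out


def variant_label(v: Variant, model: Optional[GeneModel] = None) -> str:
    """Canonical label: c.-prefixed inside the CDS, g.-prefixed outside.

    Deletions and insertions carry their LENGTH in the label (e.g. ins35);
    the actual sequence stays on the Variant.
    """
    prefix, lo, hi = _label_coords(v, model)
    if v.kind == "SNV":
        return f"{prefix}{lo}{v.ref_allele}>{v.alt_allele}"
    if v.kind == "DEL":
        n = len(v.ref_allele)
        if n == 1:
            return f"{prefix}{lo}del1"
        return f"{prefix}{lo}_{hi}del{n}"
    return f"{prefix}{lo}_{hi}ins{len(v.alt_allele)}"


def _label_coords(v: Variant, model: Optional[GeneModel]) -> tuple[str, int, int]:
    """(prefix, first, last) 1-based label coordinates for a variant."""
    if v.kind == "SNV":
        ref_lo = ref_hi = v.start
    elif v.kind == "DEL":
        ref_lo, ref_hi = v.start, v.start + len(v.ref_allele) - 1
    else:  # INS: flanking bases
        ref_lo, ref_hi = v.start - 1, v.start
    if model is not None:
        c_lo = model.ref_to_cds(ref_lo)
        c_hi = model.ref_to_cds(ref_hi)
        if c_lo is not None and c_hi is not None:
            lo, hi = sorted((c_lo, c_hi))
            return "c.", lo, hi
    return "g.", ref_lo + 1, ref_hi + 1


def annotate_variant(
    v: Variant,
    model: Optional[GeneModel] = None,
    reference: Optional[Reference] = None,
) -> tuple[str, str]:
    """Return (cds_label, aa_label) for one variant.

    aa labels use single-letter code ``<ref><codon><alt>`` for SNVs;
    frame-preserving indels get "del"/"ins" markers, frame-shifting ones
    "fs". Outside the CDS the aa label is empty.
    """
    cds_label = variant_label(v, model)
    if model is None or reference is None or not cds_label.startswith("c."):
        return cds_label, ""
    if v.kind == "SNV":
        cpos = model.ref_to_cds(v.start)
        codon_no = model.codon_of(cpos)
        aa = _codon_substitution_label(model, reference, codon_no, {cpos: v})
        return cds_label, aa
    length = len(v.ref_allele) if v.kind == "DEL" else len(v.alt_allele)
    marker = ("del" if v.kind == "DEL" else "ins") if length % 3 == 0 else "fs"
    cpos = model.ref_to_cds(v.positions()[0])
    codon_no = model.codon_of(cpos) if cpos is not None else 0
    return cds_label, f"{codon_no}{marker}" if codon_no else marker


def annotate_combined(
    cv: CombinedVariant,
    model: GeneModel,
    reference: Reference,
) -> tuple[str, str]:
    """(combined cds label, aa label) for a same-codon / consecutive group."""
    cds_label = cv.combined_label(model)
    if any(m.kind != "SNV" for m in cv.members):
        return cds_label, ""
    subs: dict[int, Variant] = {}
    codons = set()
    for m in cv.members:
        cpos = model.ref_to_cds(m.start)
        if cpos is None:
            return cds_label, ""
        subs[cpos] = m
        codons.add(model.codon_of(cpos))
    if len(codons) != 1:
        parts = [annotate_variant(m, model, reference)[1] for m in cv.members]
        return cds_label, "+".join(p for p in parts if p)
    codon_no = codons.pop()
    return cds_label, _codon_substitution_label(model, reference, codon_no, subs)


def _codon_substitution_label(
    model: GeneModel, reference: Reference, codon_no: int, subs: dict[int, Variant]
) -> str:
    cds = model.cds_sequence(reference)
    c1, _, c3 = model.codon_cds_positions(codon_no)
    if c3 > len(cds):
        return ""  # trailing partial codon
    ref_codon = cds[c1 - 1 : c3]
    alt = list(ref_codon)
    for cpos, v in subs.items():
        base = v.alt_allele
        if model.strand == "-":
            base = base.translate(str.maketrans("ACGTN", "TGCAN"))
        alt[cpos - c1] = base
    return f"{_translate_codon(ref_codon)}{codon_no}{_translate_codon(''.join(alt))}"


# -- selection labels ---------------------------------------------------------

_SNV_RE = re.compile(r"^(?:(c|g)\.)?(\d+)([ACGTN])>([ACGTN])$")
_DEL_RE = re.compile(r"^(?:(c|g)\.)?(\d+)(?:_(\d+))?del(\d+)?$")
_INS_RE = re.compile(r"^(?:(c|g)\.)?(\d+)_(\d+)ins(\d+|[ACGTN]+)$")


@dataclass(frozen=True)
class SelectionKey:
    """Parsed form of one selection-list line; matches concrete Variants.

    Insertion labels carry only a length, so an INS key matches any inserted
    sequence of that length at the position.
    """

    kind: str
    system: str  # "c" or "g"
    start: int  # 1-based label coordinate (first position of the label)
    length: int  # 1 for SNV; deleted/inserted length otherwise
    ref_allele: str = ""
    alt_allele: str = ""  # SNV alt, or INS sequence when given

    def matches(self, v: Variant, model: Optional[GeneModel] = None) -> bool:
        if v.kind != self.kind:
            return False
        prefix, lo, hi = _label_coords(v, model if self.system == "c" else None)
        if prefix.rstrip(".") != self.system:
            return False
        if self.kind == "SNV":
            return lo == self.start and v.ref_allele == self.ref_allele and v.alt_allele == self.alt_allele
        if self.kind == "DEL":
            return lo == self.start and len(v.ref_allele) == self.length
        if lo != self.start or len(v.alt_allele) != self.length:
            return False
        return not self.alt_allele or v.alt_allele == self.alt_allele


def parse_variant_label(text: str) -> SelectionKey:
    """Parse one canonical label ("c."-prefixed, "g."-prefixed, or bare).

    Bare labels default to the "c." coordinate system.
    """
    text = text.strip().replace(" ", "")
    m = _SNV_RE.match(text)
    if m:
        system = m.group(1) or "c"
        return SelectionKey(kind="SNV", system=system, start=int(m.group(2)), length=1,
                            ref_allele=m.group(3), alt_allele=m.group(4))
    m = _DEL_RE.match(text)
    if m:
        system = m.group(1) or "c"
        start = int(m.group(2))
        end = int(m.group(3)) if m.group(3) else start
        length = int(m.group(4)) if m.group(4) else end - start + 1
        if end - start + 1 != length:
            raise ValueError(f"deletion span {start}_{end} inconsistent with length {length}")
        return SelectionKey(kind="DEL", system=system, start=start, length=length)
    m = _INS_RE.match(text)
    if m:
        system = m.group(1) or "c"
        left, right = int(m.group(2)), int(m.group(3))
        if right != left + 1:
            raise ValueError(f"insertion flanks must be adjacent, got {left}_{right}")
        spec = m.group(4)
        if spec.isdigit():
            return SelectionKey(kind="INS", system=system, start=left, length=int(spec))
        return SelectionKey(kind="INS", system=system, start=left, length=len(spec), alt_allele=spec)
    raise ValueError(f"cannot parse variant label {text!r}")


def resolve_selection(
    keys: Sequence[SelectionKey],
    detected: Iterable[Variant],
    model: Optional[GeneModel] = None,
) -> list[Variant]:
    """Map selection keys onto detected variants; unmatched keys are dropped
    with the caller expected to warn (a selected variant never observed
    cannot appear in any haplotype row)."""
    detected = list(detected)
    out: list[Variant] = []
    seen: set[Variant] = set()
    for key in keys:
        for v in detected:
            if v not in seen and key.matches(v, model):
                out.append(v)
                seen.add(v)
    return out
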