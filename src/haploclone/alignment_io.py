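"""Input parsing: reference FASTA, SAM alignments, CDS annotation, amplicon BED.

All internal coordinates are 0-based half-open; c./g. labels produced by the
:mod:`haploclone.variants` module are 1-based for reporting.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

#: CIGAR op codes (pysam numeric) mapped to the internal alphabet.
#: M/=/X collapse to "M"; H is dropped (consumes nothing we track);
#: P (pad) is kept through parsing and ignored by the variant caller,
#: which makes the padded and unpadded dialects of the same alignment
#: coordinate-identical.
_CIGAR_MAP = {0: "M", 1: "I", 2: "D", 4: "S", 6: "P", 7: "M", 8: "M"}

_QUERY_CONSUMING = {"M", "I", "S"}
_REF_CONSUMING = {"M", "D"}


class FormatError(ValueError):
    """Raised on malformed or out-of-contract input files."""


@dataclass(frozen=True)
class Reference:
    """A single reference sequence, uppercase, alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """CDS definition mapping reference positions to coding (c.) coordinates.

    ``cds_intervals`` are sorted, non-overlapping, 0-based half-open intervals
    on the reference; the first coding base (5' end of the CDS in reading
    direction) is c.1.
    """

    cds_intervals: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        iv = self.cds_intervals
        if not iv or any(e <= s for s, e in iv):
            raise ValueError("CDS intervals must be non-empty")
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError("CDS intervals must be sorted and non-overlapping")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def ref_to_cds(self, pos: int) -> Optional[int]:
        """1-based c. position for a 0-based reference position, or None."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                fwd = offset + (pos - s) + 1
                return fwd if self.strand == "+" else self.cds_length - fwd + 1
            offset += e - s
        return None

    def cds_to_ref(self, cpos: int) -> int:
        """0-based reference position for a 1-based c. position."""
        if not 1 <= cpos <= self.cds_length:
            raise ValueError(f"c.{cpos} outside CDS of length {self.cds_length}")
        fwd = cpos if self.strand == "+" else self.cds_length - cpos + 1
        offset = 0
        for s, e in self.cds_intervals:
            if fwd <= offset + (e - s):
                return s + (fwd - offset - 1)
            offset += e - s
        raise AssertionError("unreachable")

    def codon_of(self, cpos: int) -> int:
        """1-based codon number of a 1-based c. position."""
        return (cpos - 1) // 3 + 1

    def codon_cds_positions(self, codon: int) -> tuple[int, int, int]:
        base = (codon - 1) * 3
        return (base + 1, base + 2, base + 3)

    def cds_sequence(self, reference: Reference) -> str:
        parts = [reference.sequence[s:e] for s, e in self.cds_intervals]
        seq = "".join(parts)
        if self.strand == "-":
            seq = _revcomp(seq)
        return seq


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Amplicon:
    """One fragment type of the design: ≥1 reference segments it covers.

    Two segments with a gap model a mate pair reading both ends of a long
    amplicon without covering the middle.
    """

    label: str
    segments: tuple[tuple[int, int], ...]

    def covers_positions(self, positions: Iterable[int]) -> bool:
        from . import _intervals

        return _intervals.contains_all(self.segments, positions)


@dataclass(frozen=True)
class AmpliconDesign:
    amplicons: tuple[Amplicon, ...]

    def __len__(self) -> int:
        return len(self.amplicons)

    def region(self) -> tuple[tuple[int, int], ...]:
        from . import _intervals

        return _intervals.merge(s for a in self.amplicons for s in a.segments)


@dataclass(frozen=True)
class ReadAlignment:
    """One usable SAM record in internal form.

    ``operations`` is an ordered list of (op, length) with op in
    {M, I, D, S, P}; M covers both match and mismatch.
    """

    query_name: str
    mate_index: int  # 1, 2, or 0 for unpaired
    ref_start: int
    operations: tuple[tuple[str, int], ...]
    query_sequence: str
    flags: int = 0

    def query_length(self) -> int:
        return sum(n for op, n in self.operations if op in _QUERY_CONSUMING)

    def reference_length(self) -> int:
        return sum(n for op, n in self.operations if op in _REF_CONSUMING)

    def reference_end(self) -> int:
        return self.ref_start + self.reference_length()


@dataclass
class LoadReport:
    """Exact record accounting for one parse pass."""

    records_used: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_other_reference: int = 0
    skipped_malformed: int = 0
    malformed_details: list[str] = field(default_factory=list)

    @property
    def records_skipped(self) -> int:
        return (
            self.skipped_unmapped
            + self.skipped_secondary
            + self.skipped_supplementary
            + self.skipped_other_reference
            + self.skipped_malformed
        )

    @property
    def records_in(self) -> int:
        return self.records_used + self.records_skipped


def load_reference(path: str | os.PathLike) -> Reference:
    """Load the first FASTA record, uppercased; warn if the file has more."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        log.warning("%s contains %d records; using the first (%s)", path, len(records), records[0].id)
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(f"invalid characters {sorted(bad)} in reference {rec.id!r}")
    return Reference(name=rec.id, sequence=seq)


def _ensure_header(path: str) -> str:
    """pysam needs @SQ lines; synthesize a header for headerless SAM files."""
    with open(path) as fh:
        head = fh.read(65536)
    if any(line.startswith("@SQ") for line in head.splitlines()):
        return path
    # find the reference name used by the records (column 3)
    names = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 3 and cols[2] != "*":
                names.add(cols[2])
    tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    for name in sorted(names):
        tmp.write(f"@SQ\tSN:{name}\tLN:536870911\n")
    with open(path) as fh:
        for line in fh:
            tmp.write(line)
    tmp.close()
    return tmp.name


def parse_alignment(
    path: str | os.PathLike,
    reference: Reference,
    max_malformed_fraction: float = 0.01,
) -> tuple[list[ReadAlignment], LoadReport]:
    """Parse a SAM file (unpadded or padded dialect) into ReadAlignments.

    Unmapped, secondary and supplementary records are skipped and counted.
    Records on other references are skipped. A record whose CIGAR is
    inconsistent with its sequence length is skipped; if more than
    ``max_malformed_fraction`` of all records are malformed the parse aborts.
    """
    actual = _ensure_header(str(path))
    report = LoadReport()
    reads: list[ReadAlignment] = []
    try:
        sam = pysam.AlignmentFile(actual, "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot read SAM file {path}: {exc}") from exc
    with sam:
        for rec in sam:
            if rec.is_unmapped:
                report.skipped_unmapped += 1
                continue
            if rec.is_secondary:
                report.skipped_secondary += 1
                continue
            if rec.is_supplementary:
                report.skipped_supplementary += 1
                continue
            if rec.reference_name != reference.name:
                report.skipped_other_reference += 1
                continue
            try:
                aln = _convert_record(rec, reference)
            except FormatError as exc:
                report.skipped_malformed += 1
                if len(report.malformed_details) < 20:
                    report.malformed_details.append(f"{rec.query_name}: {exc}")
                continue
            reads.append(aln)
            report.records_used += 1
    if actual != str(path):
        os.unlink(actual)
    if report.records_in and report.skipped_malformed / report.records_in > max_malformed_fraction:
        raise FormatError(
            f"{report.skipped_malformed}/{report.records_in} malformed records in {path}: "
            + "; ".join(report.malformed_details[:5])
        )
    return reads, report


def _convert_record(rec: "pysam.AlignedSegment", reference: Reference) -> ReadAlignment:
    if rec.cigartuples is None or rec.query_sequence is None:
        raise FormatError("missing CIGAR or sequence")
    ops: list[tuple[str, int]] = []
    for code, n in rec.cigartuples:
        if code == 5:  # hard clip: consumes nothing tracked here
            continue
        op = _CIGAR_MAP.get(code)
        if op is None:
            raise FormatError(f"unsupported CIGAR op code {code}")
        ops.append((op, n))
    seq = rec.query_sequence.upper()
    qlen = sum(n for op, n in ops if op in _QUERY_CONSUMING)
    if qlen != len(seq):
        raise FormatError(f"CIGAR consumes {qlen} query bases but sequence has {len(seq)}")
    rlen = sum(n for op, n in ops if op in _REF_CONSUMING)
    if rec.reference_start + rlen > len(reference):
        raise FormatError("alignment extends past reference end")
    if rec.is_paired:
        mate = 1 if rec.is_read1 else 2
    else:
        mate = 0
    return ReadAlignment(
        query_name=rec.query_name,
        mate_index=mate,
        ref_start=rec.reference_start,
        operations=tuple(ops),
        query_sequence=seq,
        flags=rec.flag,
    )


def load_gene_model(
    path: str | os.PathLike,
    reference: Optional[Reference] = None,
    cds_name: Optional[str] = None,
) -> GeneModel:
    """Load a CDS definition from a GenBank flat file or a simple table.

    Tabular rows are ``CDS <start> <end> <strand> [name]`` with 1-based
    inclusive coordinates (GenBank style). With several CDS definitions,
    ``cds_name`` must pick one.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(256)
    if head.startswith("LOCUS"):
        model = _gene_model_from_genbank(path, cds_name)
    else:
        model = _gene_model_from_table(path, cds_name)
    if reference is not None:
        end = model.cds_intervals[-1][1]
        if end > len(reference):
            raise FormatError(f"CDS extends to {end} past reference end {len(reference)}")
    if model.cds_length % 3 != 0:
        log.warning(
            "CDS length %d not divisible by 3; trailing partial codon ignored for aa annotation",
            model.cds_length,
        )
    return model


def _gene_model_from_genbank(path: str, cds_name: Optional[str]) -> GeneModel:
    record = SeqIO.read(path, "genbank")
    features = [f for f in record.features if f.type == "CDS"]
    if not features:
        raise FormatError(f"no CDS feature in {path}")
    if cds_name is not None:
        named = []
        for f in features:
            labels = f.qualifiers.get("gene", []) + f.qualifiers.get("locus_tag", [])
            if cds_name in labels:
                named.append(f)
        if not named:
            raise FormatError(f"no CDS feature named {cds_name!r} in {path}")
        features = named
    if len(features) > 1:
        raise FormatError(f"{len(features)} CDS features in {path}; select one by name")
    feat = features[0]
    intervals = tuple(sorted((int(p.start), int(p.end)) for p in feat.location.parts))
    strand = "-" if feat.location.strand == -1 else "+"
    return GeneModel(cds_intervals=intervals, strand=strand)


def _gene_model_from_table(path: str, cds_name: Optional[str]) -> GeneModel:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if cols[0].upper() != "CDS" or len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 'CDS <start> <end> <strand> [name]'")
            start, end, strand = int(cols[1]), int(cols[2]), cols[3]
            name = cols[4] if len(cols) > 4 else None
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: bad coordinates {start}..{end}")
            rows.append((start - 1, end, strand, name))
    if not rows:
        raise FormatError(f"no CDS rows in {path}")
    if cds_name is not None:
        rows = [r for r in rows if r[3] == cds_name]
        if not rows:
            raise FormatError(f"no CDS named {cds_name!r} in {path}")
    if len(rows) > 1:
        raise FormatError(f"{len(rows)} CDS rows in {path}; select one by name")
    start, end, strand, _ = rows[0]
    return GeneModel(cds_intervals=((start, end),), strand=strand)


def load_amplicon_design(path: str | os.PathLike, reference: Reference) -> AmpliconDesign:
    """Load a BED file; rows sharing a name (column 4) form one amplicon."""
    groups: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least start and end")
            # chrom column is optional for a single-reference design
            if len(cols) >= 3 and not cols[0].lstrip("-").isdigit():
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else f"amplicon{lineno}"
                if chrom != reference.name:
                    raise FormatError(f"{path}:{lineno}: unknown reference {chrom!r}")
            else:
                start, end = int(cols[0]), int(cols[1])
                name = cols[2] if len(cols) > 2 else f"amplicon{lineno}"
            if start < 0 or end > len(reference) or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) outside reference of length {len(reference)}"
                )
            if name not in groups:
                groups[name] = []
                order.append(name)
            groups[name].append((start, end))
    if not groups:
        raise FormatError(f"no intervals in {path}")
    amplicons = tuple(
        Amplicon(label=name, segments=tuple(sorted(groups[name]))) for name in order
    )
    return AmpliconDesign(amplicons=amplicons)


def load_variant_selection(path: str | os.PathLike):
    """Parse a plain-text variant list (one canonical label per line).

    Returns a list of selection keys (see :mod:`haploclone.variants`);
    an empty file yields an empty selection, meaning "all detected".
    """
    from .variants import parse_variant_label

    keys = []
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                keys.append(parse_variant_label(line))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return keys
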