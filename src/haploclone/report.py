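"""Filtering, CSV export, and the end-to-end pipeline."""

from __future__ import annotations

import logging
import os
from copy import deepcopy
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .alignment_io import (
    FormatError,
    GeneModel,
    Reference,
    load_amplicon_design,
    load_gene_model,
    load_reference,
    load_variant_selection,
    parse_alignment,
)
from .haplotypes import HaplotypeTable, assemble_fragments, detect_variant_table, tabulate
from .infer import MAX_ROUNDS, MAX_VARIANTS, InferenceError, infer_scattered
from .quantify import quantify_table
from .variants import (
    Variant,
    annotate_combined,
    annotate_variant,
    call_read_variants,
    combine_variants,
    normalize_indels,
    resolve_selection,
    variant_label,
)

log = logging.getLogger(__name__)


@dataclass
class ReportRow:
    variant_labels: tuple[str, ...]
    combined_labels: tuple[str, ...]
    cds_changes: tuple[str, ...]
    aa_changes: tuple[str, ...]
    hits: int
    percentage: float
    inferred: bool


@dataclass
class CloneReport:
    rows: list[ReportRow]
    wildtype_percentage: float
    metadata: dict[str, str] = field(default_factory=dict)


def apply_threshold(table: HaplotypeTable, min_percent: float) -> HaplotypeTable:
    """Drop rows below the reporting threshold (quantified tables only)."""
    table = deepcopy(table)
    kept, dropped = [], []
    for row in table.rows:
        if row.percentage is None:
            raise ValueError("apply_threshold needs a quantified table")
        (kept if row.percentage >= min_percent else dropped).append(row)
    if dropped:
        log.info(
            "%d rows below %.2f%% threshold dropped (%d hits total)",
            len(dropped), min_percent, sum(r.hits for r in dropped),
        )
    if not kept and table.rows:
        log.warning("all %d rows fell below the %.2f%% threshold", len(table.rows), min_percent)
    table.rows = kept
    return table


def build_report(
    table: HaplotypeTable,
    model: Optional[GeneModel] = None,
    reference: Optional[Reference] = None,
    metadata: Optional[dict[str, str]] = None,
) -> CloneReport:
    """Render a quantified table: sorted rows, labels, annotation columns."""
    rows: list[ReportRow] = []
    for h in table.rows:
        labels = tuple(variant_label(v, model) for v in h.variants)
        combined = combine_variants(h.variants, model)
        combined_labels = tuple(
            cv.combined_label(model) for cv in combined if len(cv.members) > 1
        )
        cds, aa = [], []
        for cv in combined:
            if len(cv.members) > 1 and model is not None and reference is not None:
                c, a = annotate_combined(cv, model, reference)
            else:
                c, a = annotate_variant(cv.members[0], model, reference)
            cds.append(c)
            if a:
                aa.append(a)
        rows.append(
            ReportRow(
                variant_labels=labels,
                combined_labels=combined_labels,
                cds_changes=tuple(cds),
                aa_changes=tuple(aa),
                hits=h.hits,
                percentage=h.percentage if h.percentage is not None else 0.0,
                inferred=h.inferred,
            )
        )
    rows.sort(key=lambda r: (-r.percentage, r.variant_labels))
    return CloneReport(
        rows=rows,
        wildtype_percentage=table.wildtype_percentage or 0.0,
        metadata=dict(metadata or {}),
    )


_COLUMNS = ("variants", "combined", "cds_changes", "aa_changes", "hits", "percentage", "inferred")


def export_report(report: CloneReport, path: str | os.PathLike) -> None:
    """Write the report as CSV: '#' metadata lines, header, rows, wt last.

    Output is byte-identical across runs on identical inputs (fixed float
    formatting, stable sort, no timestamps).
    """
    lines = []
    for key in sorted(report.metadata):
        lines.append(f"# {key}={report.metadata[key]}")
    lines.append(",".join(_COLUMNS))
    for r in report.rows:
        lines.append(
            ",".join(
                [
                    _quote(", ".join(r.variant_labels)),
                    _quote(", ".join(r.combined_labels)),
                    _quote(", ".join(r.cds_changes)),
                    _quote(", ".join(r.aa_changes)),
                    str(r.hits),
                    f"{r.percentage:.1f}",
                    "yes" if r.inferred else "no",
                ]
            )
        )
    lines.append(f'"wt",,,,,{report.wildtype_percentage:.1f},no')
    with open(str(path), "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


def _quote(cell: str) -> str:
    return '"' + cell.replace('"', '""') + '"'


def parse_report(path: str | os.PathLike) -> CloneReport:
    """Reparse an exported CSV into an equal CloneReport."""
    import csv

    metadata: dict[str, str] = {}
    rows: list[ReportRow] = []
    wt = 0.0
    with open(str(path), newline="") as fh:
        data_lines = []
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    metadata[k.strip()] = v.strip()
            else:
                data_lines.append(line)
    reader = csv.reader(data_lines)
    header = next(reader)
    if tuple(header) != _COLUMNS:
        raise FormatError(f"unexpected report header {header}")
    for rec in reader:
        if rec[0] == "wt":
            wt = float(rec[5])
            continue
        rows.append(
            ReportRow(
                variant_labels=_split(rec[0]),
                combined_labels=_split(rec[1]),
                cds_changes=_split(rec[2]),
                aa_changes=_split(rec[3]),
                hits=int(rec[4]),
                percentage=float(rec[5]),
                inferred=rec[6] == "yes",
            )
        )
    return CloneReport(rows=rows, wildtype_percentage=wt, metadata=metadata)


def _split(cell: str) -> tuple[str, ...]:
    return tuple(s for s in (p.strip() for p in cell.split(",")) if s)


@dataclass
class PipelineConfig:
    sam: str
    ref: str
    out: Optional[str] = None
    annotation: Optional[str] = None
    amplicons: Optional[str] = None
    variants: Optional[str] = None
    paired: bool = False
    infer: bool = False
    min_percent: float = 1.0
    min_variant_frequency: float = 0.0
    denominator: str = "informative"
    max_rounds: int = MAX_ROUNDS
    max_clique_variants: int = MAX_VARIANTS
    seed: Optional[int] = None


class ConfigError(ValueError):
    pass


def run_pipeline(config: PipelineConfig) -> CloneReport:
    """load → call → normalize → assemble → select → tabulate/infer →
    quantify → threshold → export."""
    for label, p in (("reference", config.ref), ("alignment", config.sam)):
        if not p or not os.path.exists(p):
            raise ConfigError(f"{label} file not found: {p!r}")
    for label, p in (
        ("annotation", config.annotation),
        ("amplicons", config.amplicons),
        ("variants", config.variants),
    ):
        if p is not None and not os.path.exists(p):
            raise ConfigError(f"{label} file not found: {p!r}")
    if config.infer and config.amplicons is None:
        raise ConfigError("--infer requires an amplicon design (--amplicons)")

    reference = load_reference(config.ref)
    model = load_gene_model(config.annotation, reference) if config.annotation else None
    design = load_amplicon_design(config.amplicons, reference) if config.amplicons else None

    reads, load_report = parse_alignment(config.sam, reference)
    log.info(
        "parsed %d records: %d used, %d skipped", load_report.records_in,
        load_report.records_used, load_report.records_skipped,
    )
    observations = [
        normalize_indels(call_read_variants(r, reference), reference) for r in reads
    ]
    paired = config.paired or any(o.mate_index for o in observations)
    fragments = assemble_fragments(observations, paired=paired)
    log.info("%d fragments assembled from %d reads", len(fragments), len(observations))

    summary = detect_variant_table(fragments)
    if config.variants:
        keys = load_variant_selection(config.variants)
        selected = resolve_selection(keys, [s.variant for s in summary], model)
        if len(selected) < len(keys):
            log.warning("%d of %d selected variants never detected", len(keys) - len(selected), len(keys))
    else:
        selected = [
            s.variant for s in summary if s.frequency >= config.min_variant_frequency
        ]
    log.info("%d variants selected (of %d detected)", len(selected), len(summary))

    if config.infer:
        table = infer_scattered(
            fragments, selected, design,
            max_rounds=config.max_rounds, max_variants=config.max_clique_variants,
        )
    else:
        table = tabulate(fragments, selected)
    table = quantify_table(table, denominator_mode=config.denominator)
    table = apply_threshold(table, config.min_percent)

    metadata = {
        "version": __version__,
        "sam": os.path.basename(config.sam),
        "reference": reference.name,
        "mode": table.mode,
        "denominator": config.denominator,
        "min_percent": f"{config.min_percent:g}",
        "selected": ";".join(variant_label(v, model) for v in table.selected),
        "fragments": str(table.total_fragments),
    }
    if config.seed is not None:
        metadata["seed"] = str(config.seed)
    report = build_report(table, model, reference, metadata)
    if config.out:
        export_report(report, config.out)
    return report
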