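"""Percentage calculation and wild-type estimation for haplotype tables."""

from __future__ import annotations

import logging
from copy import deepcopy
from typing import Sequence

from .haplotypes import HaplotypeTable

log = logging.getLogger(__name__)

DENOMINATOR_MODES = ("informative", "sum_positions")


def quantify_table(table: HaplotypeTable, denominator_mode: str = "informative") -> HaplotypeTable:
    """Attach percentages to every row and estimate the wild-type fraction.

    ``informative`` (default): percentage = 100 × hits / (fragments covering
    all of the row's variant positions). ``sum_positions``: percentage =
    100 × hits / Σ per-variant coverage over the row's variants — the literal
    reading of the published formula, under which multi-variant percentages
    shrink with variant count. Rows with a zero denominator get 0% and a
    warning. Inferred tables use the per-clone unit denominator instead.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    table = deepcopy(table)
    for row in table.rows:
        if table.mode == "inferred":
            denom = table.unit_denominator or 0
        elif denominator_mode == "informative":
            denom = row.informative
        else:
            denom = sum(table.variant_coverage.get(v, 0) for v in row.variants)
        if denom <= 0:
            log.warning("row %s has zero denominator; percentage set to 0", row.variants)
            row.percentage = 0.0
        else:
            row.percentage = 100.0 * row.hits / denom
    total = sum(r.percentage for r in table.rows)
    if total > 100.0:
        log.info("row percentages sum to %.2f%% (>100%%); denominators differ per row", total)
    table.wildtype_percentage = wildtype_estimate([r.percentage for r in table.rows])
    return table


def wildtype_estimate(percentages: Sequence[float]) -> float:
    """Complement of the detected clones, clamped at zero."""
    return max(0.0, 100.0 - sum(percentages))
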