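from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from haploclone.alignment_io import GeneModel, ReadAlignment, Reference
from haploclone.simulate import random_reference, write_reference


@pytest.fixture(scope="session")
def ref924() -> Reference:
    return random_reference(924, np.random.default_rng(42))


@pytest.fixture(scope="session")
def whole_cds_model() -> GeneModel:
    return GeneModel(cds_intervals=((0, 924),), strand="+")


@pytest.fixture()
def fasta_file(tmp_path, ref924):
    path = tmp_path / "ref.fasta"
    write_reference(ref924, path)
    return str(path)


def identity_read(reference: Reference, start: int, length: int, name: str = "r1") -> ReadAlignment:
    return ReadAlignment(
        query_name=name,
        mate_index=0,
        ref_start=start,
        operations=(("M", length),),
        query_sequence=reference.sequence[start : start + length],
        flags=0,
    )


def sam_text(reads, reference: Reference, header: bool = True) -> str:
    """Hand-rolled SAM writer so parser tests don't depend on pysam output."""
    lines = []
    if header:
        lines.append(f"@SQ\tSN:{reference.name}\tLN:{len(reference)}")
    for r in reads:
        cigar = "".join(f"{n}{op}" for op, n in r.operations)
        lines.append(
            "\t".join(
                [
                    r.query_name,
                    str(r.flags),
                    reference.name,
                    str(r.ref_start + 1),
                    "60",
                    cigar,
                    "*",
                    "0",
                    "0",
                    r.query_sequence,
                    "*",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_sam(tmp_path, reads, reference, name="reads.sam", header=True) -> str:
    path = tmp_path / name
    path.write_text(sam_text(reads, reference, header=header))
    return str(path)
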