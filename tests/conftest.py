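"""Shared builders for pileup columns and reads used across the suite."""

from __future__ import annotations

import pytest

from lcsnv.pileup import PileupColumn
from lcsnv.reads import ReadRecord


def make_column(
    alleles: dict[str, tuple[int, int]],
    ref_base: str = "A",
    chrom: str = "chr1",
    pos: int = 100,
    qual: int | dict[str, int] = 30,
    novel_starts: dict[str, int] | None = None,
) -> PileupColumn:
    """Build a pileup column from per-allele (forward, reverse) counts.

    ``qual`` is the per-base quality (scalar or per-allele).  By default
    every read gets a distinct start key, so novel starts equal read
    counts; ``novel_starts`` caps the number of distinct keys per allele
    to emulate stacked (duplicate-like) reads.
    """
    col = PileupColumn(chrom=chrom, pos=pos, ref_base=ref_base)
    key_counter = 0
    for allele, (fwd, rev) in alleles.items():
        q = qual[allele] if isinstance(qual, dict) else qual
        cap = None if novel_starts is None else novel_starts.get(allele)
        added = 0
        for strand, n in (("+", fwd), ("-", rev)):
            for _ in range(n):
                if cap is not None:
                    key = ("+", 1000 + (added % cap))
                else:
                    key = (strand, key_counter)
                    key_counter += 1
                col.add_base(allele, strand, q, key)
                added += 1
    return col


def make_read(
    chrom: str = "chr1",
    start: int = 100,
    strand: str = "+",
    seq: str = "ACGT",
    qual: int = 30,
    mapq_single: int = 60,
    align_len: int | None = None,
    mismatches: int = 0,
    is_duplicate: bool = False,
    is_proper_pair: bool = True,
    is_second_in_pair: bool = False,
    mate_chrom: str = "chr1",
    mate_start: int = 300,
) -> ReadRecord:
    return ReadRecord(
        chrom=chrom,
        start=start,
        strand=strand,
        seq=seq,
        quals=tuple([qual] * len(seq)),
        mapq_single=mapq_single,
        align_len=align_len if align_len is not None else len(seq),
        mismatches=mismatches,
        is_duplicate=is_duplicate,
        is_proper_pair=is_proper_pair,
        is_second_in_pair=is_second_in_pair,
        mate_chrom=mate_chrom,
        mate_start=mate_start,
    )


@pytest.fixture
def column_factory():
    return make_column


@pytest.fixture
def read_factory():
    return make_read
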