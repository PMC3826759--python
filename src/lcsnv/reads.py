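"""Aligned-read records and their on-disk representations.

The caller consumes a minimal view of an aligned read: where it sits on the
reference, which base (and base quality) it contributes at each covered
position, and the handful of attributes the read filters and the
duplicate heuristics need (single-read mapping quality, aligned length,
mismatch count, flags, and mate coordinates).

Two sources are supported: coordinate-sorted, duplicate-marked SAM/BAM via
pysam, and a plain-text one-read-per-line fixture format used by the
simulator and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "ReadRecord",
    "read_fixture",
    "write_fixture",
    "reads_from_alignment_file",
]

#: placeholder used in the aligned-sequence string for positions the read
#: spans but does not observe (deletion / reference skip)
GAP = "-"


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One aligned read, reduced to what pileup construction needs.

    Coordinates are 1-based and fully closed.  ``seq``/``quals`` run along
    the reference from ``start``; a deletion or reference skip is padded
    with :data:`GAP` so ``seq[i]`` is always the base contributed at
    reference position ``start + i`` (or nothing, for a gap).
    """

    chrom: str
    start: int                  # 1-based leftmost aligned reference position
    strand: str                 # '+' or '-'
    seq: str                    # reference-aligned bases, GAP-padded
    quals: tuple[int, ...]      # Phred base qualities, one per seq char
    mapq_single: int            # single-read ("SM") mapping quality
    align_len: int              # aligned length in bp
    mismatches: int             # mismatches to the reference
    is_duplicate: bool = False
    is_proper_pair: bool = False
    is_second_in_pair: bool = False
    mate_chrom: str = "*"
    mate_start: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.seq) != len(self.quals):
            raise ValueError("seq and quals lengths differ")
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError("base qualities must lie in [0, 93]")

    @property
    def end(self) -> int:
        """1-based rightmost reference position spanned by the read."""
        return self.start + len(self.seq) - 1

    @property
    def five_prime_start(self) -> int:
        """5'-most aligned reference position on the read's own strand.

        Reads originating from the same source molecule share this
        coordinate, which makes (strand, five_prime_start) the key used
        for novel-start counting.
        """
        return self.start if self.strand == "+" else self.end

    def base_at(self, pos: int) -> Optional[str]:
        """Called base at 1-based reference ``pos``, or None if not covered."""
        i = pos - self.start
        if i < 0 or i >= len(self.seq):
            return None
        b = self.seq[i]
        return None if b == GAP else b

    def qual_at(self, pos: int) -> Optional[int]:
        """Phred base quality at ``pos``, or None if not covered."""
        i = pos - self.start
        if i < 0 or i >= len(self.seq) or self.seq[i] == GAP:
            return None
        return self.quals[i]


# ---------------------------------------------------------------------------
# plain-text fixture format
# ---------------------------------------------------------------------------

_FIXTURE_HEADER = (
    "chrom\tstart\tstrand\tseq\tquals\tmapq_single\talign_len\tmismatches"
    "\tflags\tmate_chrom\tmate_start"
)


def _flags_str(r: ReadRecord) -> str:
    parts = []
    if r.is_duplicate:
        parts.append("dup")
    if r.is_proper_pair:
        parts.append("proper")
    if r.is_second_in_pair:
        parts.append("second")
    return ",".join(parts) or "."


def write_fixture(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as tab-delimited text, one read per line."""
    with open(path, "w") as fh:
        fh.write(_FIXTURE_HEADER + "\n")
        for r in reads:
            quals = ",".join(str(q) for q in r.quals)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.strand}\t{r.seq}\t{quals}\t"
                f"{r.mapq_single}\t{r.align_len}\t{r.mismatches}\t"
                f"{_flags_str(r)}\t{r.mate_chrom}\t{r.mate_start}\n"
            )


def read_fixture(path: str | Path) -> list[ReadRecord]:
    """Read the plain-text fixture format written by :func:`write_fixture`."""
    out: list[ReadRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _FIXTURE_HEADER.strip():
            raise ValueError(f"unrecognized fixture header in {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 11:
                raise ValueError(f"{path}:{lineno}: expected 11 fields, got {len(f)}")
            flags = set() if f[8] == "." else set(f[8].split(","))
            out.append(
                ReadRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    strand=f[2],
                    seq=f[3],
                    quals=tuple(int(q) for q in f[4].split(",")),
                    mapq_single=int(f[5]),
                    align_len=int(f[6]),
                    mismatches=int(f[7]),
                    is_duplicate="dup" in flags,
                    is_proper_pair="proper" in flags,
                    is_second_in_pair="second" in flags,
                    mate_chrom=f[9],
                    mate_start=int(f[10]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM/BAM import
# ---------------------------------------------------------------------------

def reads_from_alignment_file(
    path: str | Path,
    region: Optional[tuple[str, int, int]] = None,
) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a SAM/BAM file via pysam.

    ``region`` is (chrom, start, end), 1-based closed.  Unmapped and
    secondary/supplementary records are skipped.  The single-read mapping
    quality is taken from the SM tag when present, else from MAPQ; the
    mismatch count from the NM tag (0 when absent).  CIGAR deletions and
    reference skips are padded with GAP so downstream pileups exclude
    them from coverage.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        overlap_only = False
        if region is not None:
            chrom, start, end = region
            try:
                it = af.fetch(chrom, start - 1, end)
            except ValueError:  # no index (plain SAM): scan and filter
                it = af.fetch(until_eof=True)
                overlap_only = True
        else:
            it = af.fetch(until_eof=True)
        for aln in it:
            if overlap_only and region is not None:
                chrom, start, end = region
                if (
                    aln.reference_name != chrom
                    or aln.reference_start is None
                    or aln.reference_start + 1 > end
                    or (aln.reference_end or 0) < start
                ):
                    continue
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rec = _record_from_pysam(aln)
            if rec is not None:
                yield rec


def _record_from_pysam(aln) -> Optional[ReadRecord]:
    seq = aln.query_sequence
    quals = aln.query_qualities
    if seq is None or quals is None or aln.cigartuples is None:
        return None
    ref_chars: list[str] = []
    ref_quals: list[int] = []
    qpos = 0
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):         # M, =, X: consumes both
            ref_chars.extend(seq[qpos : qpos + length])
            ref_quals.extend(quals[qpos : qpos + length])
            qpos += length
        elif op in (1, 4):          # I, S: query only
            qpos += length
        elif op in (2, 3):          # D, N: reference only -> gap
            ref_chars.extend(GAP * length)
            ref_quals.extend([0] * length)
    if not ref_chars:
        return None
    sm = aln.get_tag("SM") if aln.has_tag("SM") else aln.mapping_quality
    nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
    mate_chrom = "*"
    mate_start = 0
    if aln.is_paired and not aln.mate_is_unmapped:
        mate_chrom = aln.next_reference_name or "*"
        mate_start = aln.next_reference_start + 1
    return ReadRecord(
        chrom=aln.reference_name,
        start=aln.reference_start + 1,
        strand="-" if aln.is_reverse else "+",
        seq="".join(ref_chars),
        quals=tuple(int(q) for q in ref_quals),
        mapq_single=int(sm),
        align_len=sum(l for op, l in aln.cigartuples if op in (0, 7, 8)),
        mismatches=int(nm),
        is_duplicate=aln.is_duplicate,
        is_proper_pair=aln.is_proper_pair,
        is_second_in_pair=aln.is_paired and aln.is_read2,
        mate_chrom=mate_chrom,
        mate_start=mate_start,
    )
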