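"""Post-processing checks, flags, and confidence tiers.

No p-value is computed for a call.  Instead each call is annotated with
flags naming the quality criteria it fails, and confidence is assigned
from the flag set.  Somatic-type checks:

* ``COVN12`` — fewer than 12 reads coverage in the matched normal
* ``GERM``   — mutation is a known germline variant in another patient
* ``MIN``    — mutant allele also found in the filtered normal pileup
* ``MIUN``   — mutant allele found in the unfiltered non-duplicate
  normal pileup
* ``MER``    — mutant allele equals the reference base
* ``SBIAS``  — strand bias (applied to Illumina data only)

Germline-type checks: ``COVN8`` (< 8x normal coverage), ``SAN3`` (< 3
reads of the variant allele in normal), ``COVT8`` (< 8x tumor coverage),
``SAT3`` (< 3 reads of the variant allele in tumor).  Checks applied to
both: ``NNS`` (< 4 novel starts, not considering the read pair) and
``MR`` (< 5 variant reads).  A call with no failing check, at least 5
mutant reads and at least 4 novel starts is flagged ``PASS``.

Confidence: *high* for PASS; *medium* when the only somatic flag is
COVN12 (the normal simply lacks coverage, so the call may be an
under-sampled germline variant); *low* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .classify import GERMLINE, SOMATIC, JointCall
from .pileup import PileupColumn

__all__ = [
    "AnnotationThresholds",
    "DEFAULT_ANNOTATION",
    "AnnotatedCall",
    "GermlineDB",
    "annotate",
    "assign_confidence",
    "update_germline_db",
]

SOMATIC_FLAGS = {"COVN12", "GERM", "MIN", "MIUN", "MER", "SBIAS"}
GERMLINE_FLAGS = {"COVN8", "SAN3", "COVT8", "SAT3"}
SHARED_FLAGS = {"NNS", "MR"}
ALL_FLAGS = SOMATIC_FLAGS | GERMLINE_FLAGS | SHARED_FLAGS | {"PASS"}


@dataclass(frozen=True)
class AnnotationThresholds:
    """Flag thresholds; each names the smallest acceptable value."""

    min_normal_coverage_somatic: int = 12   # COVN12
    min_normal_coverage_germline: int = 8   # COVN8
    min_same_allele_normal: int = 3         # SAN3
    min_tumor_coverage_germline: int = 8    # COVT8
    min_same_allele_tumor: int = 3          # SAT3
    min_novel_starts: int = 4               # NNS
    min_mutant_reads: int = 5               # MR
    sbias_min_variant_reads: int = 5        # SBIAS: one-sided evidence floor
    sbias_min_opposite_coverage: int = 5    # SBIAS: opposite strand must be sampled


DEFAULT_ANNOTATION = AnnotationThresholds()


@dataclass
class AnnotatedCall:
    """A joint call plus its flag set, evidence counts, and confidence."""

    call: JointCall
    flags: set[str]
    mutant_read_count: int
    novel_start_count: int
    confidence: str            # "high" | "medium" | "low"
    tumor_col: Optional[PileupColumn] = None
    normal_col: Optional[PileupColumn] = None

    @property
    def is_somatic(self) -> bool:
        return self.call.classification == SOMATIC

    @property
    def variant_allele(self) -> Optional[str]:
        return _variant_allele(self.call)


class GermlineDB:
    """Shared database of germline variants seen in other patients.

    Stored as tab-delimited text: chrom, pos, ref, alt, observation
    count.  Lookup is exact on (chrom, pos, alt).  High-quality germline
    calls from each run can be appended so the database grows with each
    patient analyzed.
    """

    def __init__(self) -> None:
        self._records: dict[tuple[str, int, str], tuple[str, int]] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._records

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        key = (chrom, pos, alt)
        prev = self._records.get(key)
        if prev is None:
            self._records[key] = (ref, 1)
        else:
            self._records[key] = (prev[0], prev[1] + 1)

    def merge_call(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        """Insert if absent; idempotent for repeat submissions of one call."""
        if (chrom, pos, alt) not in self._records:
            self._records[(chrom, pos, alt)] = (ref, 1)

    @classmethod
    def load(cls, path: str | Path) -> "GermlineDB":
        db = cls()
        p = Path(path)
        if not p.exists():
            return db
        with open(p) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, ref, alt, count = line.rstrip("\n").split("\t")
                db._records[(chrom, int(pos), alt)] = (ref, int(count))
        return db

    def save(self, path: str | Path) -> None:
        """Write atomically (temp file + rename)."""
        p = Path(path)
        tmp = p.with_suffix(p.suffix + ".tmp")
        with open(tmp, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tcount\n")
            for (chrom, pos, alt), (ref, count) in sorted(self._records.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{count}\n")
        tmp.replace(p)


def _variant_allele(call: JointCall) -> Optional[str]:
    """The allele whose evidence the shared checks count.

    Somatic: the mutant allele.  Germline: the non-reference allele of
    the tumor genotype (falling back to the normal's), since germline
    variants are expected in both samples.
    """
    if call.classification == SOMATIC:
        return call.mutant_allele
    for gt in (call.tumor_gt, call.normal_gt):
        for a in gt.alleles:
            if a != call.ref_base:
                return a
    return None


def annotate(
    call: JointCall,
    tumor_col: PileupColumn,
    normal_col: PileupColumn,
    normal_unfiltered_col: Optional[PileupColumn],
    db: Optional[GermlineDB] = None,
    platform: str = "illumina",
    thresholds: AnnotationThresholds = DEFAULT_ANNOTATION,
) -> AnnotatedCall:
    """Run every applicable post-processing check and assign confidence.

    ``normal_unfiltered_col`` is the column from the unfiltered
    (non-duplicate) normal pileup; ``None`` means no read covered the
    position there.  All failing checks are recorded, not just the
    first.  Flags valid only for the other variant type are never
    applied.
    """
    t = thresholds
    if tumor_col.pos != call.pos or normal_col.pos != call.pos:
        raise ValueError("pileup column position does not match call")
    if normal_unfiltered_col is not None and normal_unfiltered_col.pos != call.pos:
        raise ValueError("unfiltered normal column position does not match call")

    allele = _variant_allele(call)
    mutant_reads = tumor_col.count(allele) if allele else 0
    novel_starts = tumor_col.novel_start_count(allele) if allele else 0

    flags: set[str] = set()
    if call.classification == SOMATIC:
        if normal_col.coverage < t.min_normal_coverage_somatic:
            flags.add("COVN12")
        if allele is not None and allele == call.ref_base:
            flags.add("MER")
        if allele is not None:
            if normal_col.count(allele) >= 1:
                flags.add("MIN")
            if (
                normal_unfiltered_col is not None
                and normal_unfiltered_col.count(allele) >= 1
            ):
                flags.add("MIUN")
            if db is not None and (call.chrom, call.pos, allele) in db:
                flags.add("GERM")
        if platform.lower() == "illumina" and allele is not None:
            fwd = tumor_col.count_fwd.get(allele, 0)
            rev = tumor_col.count_rev.get(allele, 0)
            total_fwd = sum(tumor_col.count_fwd.values())
            total_rev = sum(tumor_col.count_rev.values())
            one_sided = (fwd == 0) != (rev == 0)
            if one_sided and fwd + rev >= t.sbias_min_variant_reads:
                opposite = total_rev if rev == 0 else total_fwd
                if opposite >= t.sbias_min_opposite_coverage:
                    flags.add("SBIAS")
    else:
        if normal_col.coverage < t.min_normal_coverage_germline:
            flags.add("COVN8")
        if tumor_col.coverage < t.min_tumor_coverage_germline:
            flags.add("COVT8")
        if allele is not None:
            if normal_col.count(allele) < t.min_same_allele_normal:
                flags.add("SAN3")
            if tumor_col.count(allele) < t.min_same_allele_tumor:
                flags.add("SAT3")

    if novel_starts < t.min_novel_starts:
        flags.add("NNS")
    if mutant_reads < t.min_mutant_reads:
        flags.add("MR")

    if not flags:
        flags.add("PASS")

    return AnnotatedCall(
        call=call,
        flags=flags,
        mutant_read_count=mutant_reads,
        novel_start_count=novel_starts,
        confidence=assign_confidence(flags),
        tumor_col=tumor_col,
        normal_col=normal_col,
    )


def assign_confidence(flags: set[str]) -> str:
    """Map a flag set to a confidence tier.

    PASS alone is high confidence; COVN12 alone is medium (the matched
    normal lacks adequate coverage, so the call may yet prove germline);
    anything else is low.
    """
    if flags == {"PASS"}:
        return "high"
    if flags == {"COVN12"}:
        return "medium"
    return "low"


def update_germline_db(db: GermlineDB, calls: Iterable[AnnotatedCall]) -> GermlineDB:
    """Append flag-free germline calls to the shared database.

    Only clean (PASS) germline calls are considered high quality enough
    to export.  Idempotent: re-appending the same call does not grow the
    database.
    """
    for ac in calls:
        if ac.call.classification != GERMLINE:
            continue
        if ac.flags != {"PASS"}:
            continue
        allele = ac.variant_allele
        if allele is None:
            continue
        db.merge_call(ac.call.chrom, ac.call.pos, ac.call.ref_base, allele)
    return db
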