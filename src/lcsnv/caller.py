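"""End-to-end joint calling: reads in, annotated variant calls out.

The pipeline builds three pileups over the analyzed region — filtered
tumor, filtered normal, and unfiltered non-duplicate normal — then, at
every position where any sample shows a candidate non-reference allele,
calls genotypes in both samples, classifies the pair as germline or
somatic, and runs the post-processing checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotate import (
    DEFAULT_ANNOTATION,
    AnnotatedCall,
    AnnotationThresholds,
    GermlineDB,
    annotate,
)
from .classify import NoCallError, classify
from .filters import FilterSpec
from .genotype import DEFAULT_THRESHOLDS, EvidenceThresholds, call_genotype
from .pileup import PileupColumn, build_pileup
from .reads import ReadRecord

__all__ = ["CallStats", "call_region", "call_from_pileups"]

log = logging.getLogger("lcsnv")


@dataclass
class CallStats:
    """Per-stage counters emitted to the log after a run."""

    positions_piled: int = 0
    candidates: int = 0
    skipped_no_call: int = 0
    germline: int = 0
    somatic: int = 0
    by_confidence: dict[str, int] = field(default_factory=dict)


def call_region(
    tumor_reads: Sequence[ReadRecord],
    normal_reads: Sequence[ReadRecord],
    region: tuple[str, int, int],
    reference: str,
    filter_spec: Optional[FilterSpec],
    germline_db: Optional[GermlineDB] = None,
    platform: str = "illumina",
    evidence: EvidenceThresholds = DEFAULT_THRESHOLDS,
    annotation: AnnotationThresholds = DEFAULT_ANNOTATION,
    stats: Optional[CallStats] = None,
) -> list[AnnotatedCall]:
    """Call and annotate all variant positions in ``region``.

    ``reference`` is the region's reference sequence.  Candidate
    positions are those where the tumor or the normal filtered pileup
    carries a non-reference allele at or above the global read trigger;
    positions where either genotype cannot be called are skipped with a
    logged reason.  Returned calls are sorted by position and include
    both somatic and germline variants (positions homozygous reference
    in both samples are not reported).
    """
    tumor_pile = build_pileup(tumor_reads, region, filter_spec, reference)
    normal_pile = build_pileup(normal_reads, region, filter_spec, reference)
    normal_unf_pile = build_pileup(normal_reads, region, None, reference)
    return call_from_pileups(
        tumor_pile,
        normal_pile,
        normal_unf_pile,
        region,
        germline_db=germline_db,
        platform=platform,
        evidence=evidence,
        annotation=annotation,
        stats=stats,
    )


def call_from_pileups(
    tumor_pile: Sequence[PileupColumn],
    normal_pile: Sequence[PileupColumn],
    normal_unf_pile: Sequence[PileupColumn],
    region: tuple[str, int, int],
    germline_db: Optional[GermlineDB] = None,
    platform: str = "illumina",
    evidence: EvidenceThresholds = DEFAULT_THRESHOLDS,
    annotation: AnnotationThresholds = DEFAULT_ANNOTATION,
    stats: Optional[CallStats] = None,
) -> list[AnnotatedCall]:
    """As :func:`call_region`, starting from prebuilt pileups."""
    if stats is None:
        stats = CallStats()

    tumor_by_pos = {c.pos: c for c in tumor_pile}
    normal_by_pos = {c.pos: c for c in normal_pile}
    normal_unf_by_pos = {c.pos: c for c in normal_unf_pile}
    stats.positions_piled = len(tumor_by_pos | normal_by_pos)

    trigger = evidence.global_min_reads
    candidates: set[int] = set()
    for cols in (tumor_by_pos, normal_by_pos):
        for pos, col in cols.items():
            ref = col.ref_base
            for a in "ACGT":
                if a != ref and col.count(a) >= trigger:
                    candidates.add(pos)
                    break

    out: list[AnnotatedCall] = []
    for pos in sorted(candidates):
        t_col = tumor_by_pos.get(pos)
        n_col = normal_by_pos.get(pos)
        if t_col is None or n_col is None:
            stats.skipped_no_call += 1
            log.debug("%s:%d skipped: no coverage in both samples", region[0], pos)
            continue
        stats.candidates += 1
        t_gt = call_genotype(t_col, evidence)
        n_gt = call_genotype(n_col, evidence)
        try:
            joint = classify(
                n_gt, t_gt, t_col.ref_base, chrom=region[0], pos=pos
            )
        except NoCallError as exc:
            stats.skipped_no_call += 1
            log.debug("skipped: %s", exc)
            continue
        # hom-ref in both samples: nothing to report
        ref = t_col.ref_base
        if (
            joint.classification == "Germline"
            and t_gt.zygosity == "Hom"
            and n_gt.zygosity == "Hom"
            and set(t_gt.alleles) == {ref}
            and set(n_gt.alleles) == {ref}
        ):
            continue
        ac = annotate(
            joint,
            t_col,
            n_col,
            normal_unf_by_pos.get(pos),
            db=germline_db,
            platform=platform,
            thresholds=annotation,
        )
        out.append(ac)
        if ac.is_somatic:
            stats.somatic += 1
        else:
            stats.germline += 1
        stats.by_confidence[ac.confidence] = stats.by_confidence.get(ac.confidence, 0) + 1

    log.info(
        "piled %d positions, %d candidates, %d germline, %d somatic, tiers=%s",
        stats.positions_piled,
        stats.candidates,
        stats.germline,
        stats.somatic,
        stats.by_confidence,
    )
    return out
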