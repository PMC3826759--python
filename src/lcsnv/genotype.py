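"""Minimum-evidence genotype calling from a single sample's pileup column.

The caller is deliberately heuristic: instead of a genotype likelihood it
applies coverage-banded minimum-evidence rules chosen to keep sensitivity
high when the mutant allele fraction is diluted by low tumor cellularity.

An allele is *supported* when both a read-count requirement and a
base-quality-fraction requirement hold:

==============  =======================================  =====================
coverage band   read-count requirement                   quality-fraction req.
==============  =======================================  =====================
<= 20x          >= 3 reads                               >= 10% of column qual
> 20x, <= 50x   >= 4 reads                               >= 10%
> 50x           >= 5% of reads (one strand) or >= 2.5%   >= 10%, relaxed to
                (both strands), never fewer than 3       >= 5% on both strands
==============  =======================================  =====================

In the deepest band the fractional rules replace the absolute count, but
a floor of 3 reads always applies — the global trigger is a minimum of
3 reads of the same allele.  The two most common alleles are then
examined: if both are supported the position is heterozygous, otherwise
homozygous for the single supported allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .pileup import PileupColumn

__all__ = [
    "EvidenceThresholds",
    "DEFAULT_THRESHOLDS",
    "EvidenceResult",
    "GenotypeCall",
    "evidence_check",
    "call_genotype",
]


@dataclass(frozen=True)
class EvidenceThresholds:
    """Tunable evidence minima; defaults follow the banded rules above."""

    min_reads_low: int = 3          # coverage <= mid_cov_ceiling
    min_reads_mid: int = 4          # mid band and the floor above high_cov_floor
    mid_cov_ceiling: int = 20       # "over 20x" is strict: band switches at 21
    high_cov_floor: int = 50        # "above 50x" is strict: band switches at 51
    min_fraction_single_strand: float = 0.05
    min_fraction_both_strands: float = 0.025
    min_qual_fraction: float = 0.10
    min_qual_fraction_both_strands_high_cov: float = 0.05
    global_min_reads: int = 3       # unconditional trigger floor

    def __post_init__(self) -> None:
        if self.min_reads_low < 1 or self.min_reads_mid < 1:
            raise ValueError("minimum read counts must be >= 1")
        for f in (
            self.min_fraction_single_strand,
            self.min_fraction_both_strands,
            self.min_qual_fraction,
            self.min_qual_fraction_both_strands_high_cov,
        ):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")


DEFAULT_THRESHOLDS = EvidenceThresholds()


@dataclass(frozen=True)
class EvidenceResult:
    passed: bool
    band: str                  # "<=20", ">20,<=50", ">50"
    reason: Optional[str]      # first failing requirement, None on pass


@dataclass(frozen=True)
class GenotypeCall:
    """1–2 alleles with zygosity; ``is_call`` False marks a no-call."""

    alleles: tuple[str, ...]
    zygosity: str              # "Hom" or "Het"
    evidence: dict[str, EvidenceResult]
    is_call: bool = True

    @property
    def genotype(self) -> str:
        if not self.is_call:
            return "./."
        if self.zygosity == "Het":
            return f"{self.alleles[0]}/{self.alleles[1]}"
        return f"{self.alleles[0]}/{self.alleles[0]}"

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)

    def __eq__(self, other) -> bool:  # genotype identity, order-free for hets
        if not isinstance(other, GenotypeCall):
            return NotImplemented
        return (
            self.is_call == other.is_call
            and self.zygosity == other.zygosity
            and self.allele_set == other.allele_set
        )

    def __hash__(self) -> int:
        return hash((self.is_call, self.zygosity, self.allele_set))


NO_CALL = GenotypeCall(alleles=(), zygosity="Hom", evidence={}, is_call=False)


def _band(coverage: int, t: EvidenceThresholds) -> str:
    if coverage <= t.mid_cov_ceiling:
        return "<=20"
    if coverage <= t.high_cov_floor:
        return ">20,<=50"
    return ">50"


def evidence_check(
    column: PileupColumn,
    allele: str,
    thresholds: EvidenceThresholds = DEFAULT_THRESHOLDS,
) -> EvidenceResult:
    """Decide whether ``allele`` meets the banded minimum-evidence rules.

    Returns pass/fail with the coverage band used and, on failure, the
    first failing requirement.
    """
    t = thresholds
    cov = column.coverage
    count = column.count(allele)
    band = _band(cov, t)
    both = column.on_both_strands(allele)

    if count == 0:
        return EvidenceResult(False, band, "no supporting reads")

    if band == "<=20":
        if count < t.min_reads_low:
            return EvidenceResult(
                False, band, f"{count} reads < minimum {t.min_reads_low}"
            )
    elif band == ">20,<=50":
        if count < t.min_reads_mid:
            return EvidenceResult(
                False, band, f"{count} reads < minimum {t.min_reads_mid}"
            )
    else:
        if count < t.global_min_reads:
            return EvidenceResult(
                False, band, f"{count} reads < global minimum {t.global_min_reads}"
            )
        frac = count / cov
        needed = t.min_fraction_both_strands if both else t.min_fraction_single_strand
        if frac < needed:
            return EvidenceResult(
                False, band, f"allele fraction {frac:.4f} < minimum {needed}"
            )

    min_qf = t.min_qual_fraction
    if band == ">50" and both:
        min_qf = t.min_qual_fraction_both_strands_high_cov
    if column.qual_fraction(allele) < min_qf:
        return EvidenceResult(
            False,
            band,
            f"quality fraction {column.qual_fraction(allele):.4f} < minimum {min_qf}",
        )
    return EvidenceResult(True, band, None)


def call_genotype(
    column: PileupColumn,
    thresholds: EvidenceThresholds = DEFAULT_THRESHOLDS,
) -> GenotypeCall:
    """Call the genotype at one position from its pileup column.

    The two most common alleles (ties broken by summed quality, then
    alphabetically) are evidence-checked; both passing gives a
    heterozygote, exactly one a homozygote.  If neither passes, the
    position is homozygous reference when the reference base is observed,
    else a no-call.  Zero coverage is a no-call.
    """
    if column.coverage == 0:
        return NO_CALL
    ranked = column.alleles_by_evidence()
    top = ranked[:2]
    evidence = {a: evidence_check(column, a, thresholds) for a in top}
    passing = [a for a in top if evidence[a].passed]
    if len(passing) == 2:
        return GenotypeCall(alleles=tuple(top), zygosity="Het", evidence=evidence)
    if len(passing) == 1:
        return GenotypeCall(alleles=(passing[0],), zygosity="Hom", evidence=evidence)
    ref = column.ref_base
    if ref in "ACGT" and column.count(ref) > 0:
        return GenotypeCall(alleles=(ref,), zygosity="Hom", evidence=evidence)
    return NO_CALL
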