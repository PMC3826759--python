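"""Evidence rules and genotype calling, including an exhaustive
small-column cross-check against an independent re-derivation of the
printed rules."""

import itertools

import pytest

from lcsnv.genotype import (
    DEFAULT_THRESHOLDS,
    EvidenceThresholds,
    call_genotype,
    evidence_check,
)
from lcsnv.pileup import PileupColumn

from .conftest import make_column


class TestEvidenceCheck:
    def test_three_reads_suffice_at_low_coverage(self):
        col = make_column({"A": (12, 0), "G": (3, 0)}, qual={"A": 30, "G": 50})
        assert col.coverage == 15
        assert evidence_check(col, "G").passed

    def test_three_reads_fail_over_20x(self):
        col = make_column({"A": (27, 0), "G": (3, 0)}, qual={"A": 30, "G": 50})
        res = evidence_check(col, "G")
        assert not res.passed
        assert "minimum 4" in res.reason

    def test_four_reads_pass_over_20x(self):
        col = make_column({"A": (26, 0), "G": (4, 0)}, qual={"A": 30, "G": 50})
        assert evidence_check(col, "G").passed

    def test_high_coverage_single_strand_needs_five_percent(self):
        # 4 of 100 on one strand = 4% < 5% -> fail
        col = make_column({"A": (96, 0), "G": (4, 0)}, qual={"A": 30, "G": 90})
        assert not evidence_check(col, "G").passed
        # 5 of 100 = 5% with ample quality fraction -> pass
        col = make_column({"A": (95, 0), "G": (5, 0)}, qual={"A": 30, "G": 80})
        assert col.qual_fraction("G") >= 0.10
        assert evidence_check(col, "G").passed

    def test_high_coverage_both_strands_relaxed_to_two_and_a_half_percent(self):
        # 3 of 100 split 2+1 across strands = 3% >= 2.5%, qual fraction >= 5%
        col = make_column({"A": (97, 0), "G": (2, 1)}, qual={"A": 30, "G": 60})
        assert col.qual_fraction("G") >= 0.05
        assert evidence_check(col, "G").passed

    def test_zero_count_fails(self):
        col = make_column({"A": (10, 0)})
        assert not evidence_check(col, "G").passed

    def test_quality_fraction_requirement(self):
        # 3 low-quality variant reads among 12: count passes, quality
        # fraction 3*5/(9*45+3*5) ~= 3.6% < 10% -> fail
        col = make_column({"A": (9, 0), "G": (3, 0)}, qual={"A": 45, "G": 5})
        res = evidence_check(col, "G")
        assert not res.passed
        assert "quality fraction" in res.reason

    @pytest.mark.parametrize(
        "coverage,count,should_pass",
        [
            (20, 3, True),   # band boundary: 20x still uses the 3-read rule
            (21, 3, False),  # over 20x switches to 4 reads
            (21, 4, True),
            (50, 4, True),   # 50x still in the 4-read band
            (51, 3, True),   # above 50x: 3/51 = 5.9% >= 5%, floor 3 met
            (51, 2, False),  # below the unconditional 3-read floor
        ],
    )
    def test_band_boundaries_exact(self, coverage, count, should_pass):
        col = make_column(
            {"A": (coverage - count, 0), "G": (count, 0)},
            qual={"A": 30, "G": 90},
        )
        assert col.coverage == coverage
        assert evidence_check(col, "G").passed is should_pass

    def test_monotone_in_count(self):
        """If an allele passes at count k it passes at k+1, coverage fixed."""
        for cov in (15, 30, 80):
            passed_before = False
            for k in range(0, cov + 1):
                col = make_column(
                    {"A": (cov - k, 0), "G": (k // 2, k - k // 2)},
                    qual={"A": 30, "G": 60},
                )
                now = evidence_check(col, "G").passed
                if passed_before:
                    assert now, f"regression at coverage {cov}, count {k}"
                passed_before = now


class TestCallGenotype:
    def test_balanced_het(self):
        col = make_column({"A": (8, 7), "G": (7, 8)}, ref_base="A")
        gt = call_genotype(col)
        assert gt.zygosity == "Het"
        assert gt.allele_set == {"A", "G"}

    def test_pure_hom(self):
        col = make_column({"G": (15, 15)}, ref_base="A")
        gt = call_genotype(col)
        assert gt.zygosity == "Hom"
        assert gt.alleles == ("G",)

    def test_minor_allele_below_band_minimum_gives_hom(self):
        col = make_column({"A": (28, 0), "G": (2, 0)}, ref_base="A")
        gt = call_genotype(col)
        assert gt.zygosity == "Hom"
        assert gt.alleles == ("A",)

    def test_zero_coverage_is_no_call(self):
        col = PileupColumn(chrom="chr1", pos=1, ref_base="A")
        assert not call_genotype(col).is_call

    def test_no_passing_allele_falls_back_to_observed_reference(self):
        col = make_column({"A": (2, 0), "G": (1, 0)}, ref_base="A")
        gt = call_genotype(col)
        assert gt.is_call
        assert gt.alleles == ("A",)
        assert gt.zygosity == "Hom"

    def test_no_passing_allele_and_no_reference_is_no_call(self):
        col = make_column({"G": (2, 0)}, ref_base="A")
        assert not call_genotype(col).is_call

    def test_threshold_override_respected(self):
        strict = EvidenceThresholds(min_reads_low=4)
        col = make_column({"A": (12, 0), "G": (3, 0)}, ref_base="A")
        assert evidence_check(col, "G", DEFAULT_THRESHOLDS).passed
        assert not evidence_check(col, "G", strict).passed


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

QUAL = {"A": 10, "C": 20, "G": 30, "T": 40}


def _oracle_supported(counts: dict[str, int], allele: str) -> bool:
    """The printed evidence rules, re-derived from first principles for
    coverage <= 20 with single-strand columns: >= 3 reads and >= 10% of
    the column's summed base quality."""
    cov = sum(counts.values())
    count = counts[allele]
    if count < 3:
        return False
    total_q = sum(QUAL[a] * n for a, n in counts.items())
    return count * QUAL[allele] / total_q >= 0.10


def _oracle_genotype(counts: dict[str, int], ref: str):
    observed = [a for a in "ACGT" if counts[a] > 0]
    ranked = sorted(observed, key=lambda a: (-counts[a], -counts[a] * QUAL[a], a))
    top = ranked[:2]
    passing = [a for a in top if _oracle_supported(counts, a)]
    if len(passing) == 2:
        return ("Het", frozenset(top))
    if len(passing) == 1:
        return ("Hom", frozenset(passing))
    if counts[ref] > 0:
        return ("Hom", frozenset([ref]))
    return None  # no-call


def test_exhaustive_small_columns_match_oracle():
    """Every allele partition of coverage 1..12 yields the genotype an
    independent re-derivation of the rules produces."""
    checked = 0
    for cov in range(1, 13):
        for a in range(cov + 1):
            for c in range(cov - a + 1):
                for g in range(cov - a - c + 1):
                    t = cov - a - c - g
                    counts = {"A": a, "C": c, "G": g, "T": t}
                    col = make_column(
                        {al: (n, 0) for al, n in counts.items() if n > 0},
                        ref_base="A",
                        qual=QUAL,
                    )
                    expected = _oracle_genotype(counts, "A")
                    got = call_genotype(col)
                    if expected is None:
                        assert not got.is_call, counts
                    else:
                        zyg, alleles = expected
                        assert got.is_call, counts
                        assert (got.zygosity, got.allele_set) == (zyg, alleles), counts
                    checked += 1
    assert checked == sum(
        1
        for cov in range(1, 13)
        for a in range(cov + 1)
        for c in range(cov - a + 1)
        for g in range(cov - a - c + 1)
    )
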