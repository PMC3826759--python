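"""Post-processing flags, confidence tiers, and the germline database."""

import pytest

from lcsnv.annotate import (
    GermlineDB,
    annotate,
    assign_confidence,
    update_germline_db,
)
from lcsnv.classify import classify
from lcsnv.genotype import GenotypeCall

from .conftest import make_column


def gt(*alleles: str) -> GenotypeCall:
    distinct = sorted(set(alleles))
    if len(distinct) == 2:
        return GenotypeCall(alleles=tuple(distinct), zygosity="Het", evidence={})
    return GenotypeCall(alleles=(distinct[0],), zygosity="Hom", evidence={})


def somatic_call(chrom="chr1", pos=100):
    return classify(gt("A", "A"), gt("A", "G"), "A", chrom=chrom, pos=pos)


def germline_call(chrom="chr1", pos=100):
    return classify(gt("A", "G"), gt("A", "G"), "A", chrom=chrom, pos=pos)


def tumor_column(mutant=6, novel=None, depth=30):
    return make_column(
        {"A": (depth - mutant, 0), "G": (mutant // 2, mutant - mutant // 2)},
        novel_starts=None if novel is None else {"G": novel},
    )


def normal_column(depth=30, mutant=0):
    alleles = {"A": (depth - mutant, 0)}
    if mutant:
        alleles["G"] = (mutant, 0)
    return make_column(alleles)


class TestSomaticFlags:
    def test_clean_call_is_pass_high_confidence(self):
        ac = annotate(somatic_call(), tumor_column(6), normal_column(30),
                      normal_column(35), db=GermlineDB())
        assert ac.flags == {"PASS"}
        assert ac.confidence == "high"

    def test_low_normal_coverage_is_medium_confidence(self):
        ac = annotate(somatic_call(), tumor_column(6), normal_column(11),
                      normal_column(11))
        assert ac.flags == {"COVN12"}
        assert ac.confidence == "medium"

    @pytest.mark.parametrize("cov,flagged", [(11, True), (12, False)])
    def test_covn12_boundary(self, cov, flagged):
        ac = annotate(somatic_call(), tumor_column(6), normal_column(cov),
                      normal_column(cov))
        assert ("COVN12" in ac.flags) is flagged

    @pytest.mark.parametrize("novel,flagged", [(3, True), (4, False)])
    def test_novel_starts_boundary(self, novel, flagged):
        ac = annotate(somatic_call(), tumor_column(6, novel=novel),
                      normal_column(30), normal_column(30))
        assert ("NNS" in ac.flags) is flagged
        assert ac.confidence == ("low" if flagged else "high")

    @pytest.mark.parametrize("mutant,flagged", [(4, True), (5, False)])
    def test_mutant_read_boundary(self, mutant, flagged):
        ac = annotate(somatic_call(), tumor_column(mutant), normal_column(30),
                      normal_column(30))
        assert ("MR" in ac.flags) is flagged

    def test_variant_in_filtered_normal_implies_both_min_and_miun(self):
        # the unfiltered pileup is a superset of the filtered one
        ac = annotate(somatic_call(), tumor_column(6),
                      normal_column(30, mutant=1), normal_column(30, mutant=1))
        assert {"MIN", "MIUN"} <= ac.flags
        assert ac.confidence == "low"

    def test_variant_only_in_unfiltered_normal_flags_miun_only(self):
        ac = annotate(somatic_call(), tumor_column(6), normal_column(30),
                      normal_column(31, mutant=1))
        assert "MIUN" in ac.flags
        assert "MIN" not in ac.flags

    def test_germline_db_hit_flags_germ(self):
        db = GermlineDB()
        db.add("chr1", 100, "A", "G")
        ac = annotate(somatic_call(), tumor_column(6), normal_column(30),
                      normal_column(30), db=db)
        assert "GERM" in ac.flags
        # different alt at the same position does not hit
        db2 = GermlineDB()
        db2.add("chr1", 100, "A", "T")
        ac2 = annotate(somatic_call(), tumor_column(6), normal_column(30),
                       normal_column(30), db=db2)
        assert "GERM" not in ac2.flags

    def test_mutant_equal_reference_flags_mer(self):
        call = classify(gt("G", "G"), gt("A", "A"), "A", pos=100)  # mutant is ref
        t_col = make_column({"A": (20, 10)}, ref_base="A")
        ac = annotate(call, t_col, make_column({"G": (30, 0)}, ref_base="A"),
                      None)
        assert "MER" in ac.flags
        assert ac.confidence == "low"

    def test_strand_bias_illumina_only(self):
        t_col = make_column({"A": (10, 10), "G": (6, 0)})
        ac = annotate(somatic_call(), t_col, normal_column(30), normal_column(30),
                      platform="illumina")
        assert "SBIAS" in ac.flags
        ac_solid = annotate(somatic_call(), t_col, normal_column(30),
                            normal_column(30), platform="solid")
        assert "SBIAS" not in ac_solid.flags

    def test_no_strand_bias_when_opposite_strand_unsampled(self):
        # all coverage on one strand: absence of reverse variant reads
        # is uninformative
        t_col = make_column({"A": (24, 0), "G": (6, 0)})
        ac = annotate(somatic_call(), t_col, normal_column(30), normal_column(30),
                      platform="illumina")
        assert "SBIAS" not in ac.flags

    def test_position_mismatch_rejected(self):
        with pytest.raises(ValueError):
            annotate(somatic_call(pos=101), tumor_column(6), normal_column(30),
                     None)


class TestGermlineFlags:
    def test_clean_germline_is_pass(self):
        t_col = make_column({"A": (10, 5), "G": (10, 5)})
        n_col = make_column({"A": (10, 5), "G": (10, 5)})
        ac = annotate(germline_call(), t_col, n_col, n_col)
        assert ac.flags == {"PASS"}

    @pytest.mark.parametrize(
        "n_cov,t_cov,expect",
        [
            (7, 30, {"COVN8"}),           # 3 of 7 normal reads still carry the allele
            (30, 7, {"COVT8", "NNS", "MR"}),
            (8, 30, set()),
            (30, 8, {"MR"}),              # 4 variant reads in an 8x tumor
        ],
    )
    def test_coverage_and_allele_thresholds(self, n_cov, t_cov, expect):
        def half_variant(cov):
            return make_column({"A": (cov - cov // 2, 0), "G": (cov // 2, 0)})

        ac = annotate(germline_call(), half_variant(t_cov), half_variant(n_cov),
                      half_variant(n_cov))
        assert ac.flags - {"PASS"} == expect

    def test_somatic_only_checks_not_applied_to_germline(self):
        # variant present in normal is definitional for germline, not a flag
        t_col = make_column({"A": (10, 5), "G": (10, 5)})
        n_col = make_column({"A": (10, 5), "G": (10, 5)})
        ac = annotate(germline_call(), t_col, n_col, n_col)
        assert not {"MIN", "MIUN", "COVN12", "GERM", "MER", "SBIAS"} & ac.flags


class TestConfidence:
    def test_tiers(self):
        assert assign_confidence({"PASS"}) == "high"
        assert assign_confidence({"COVN12"}) == "medium"
        assert assign_confidence({"MIN", "NNS"}) == "low"
        assert assign_confidence({"COVN12", "MR"}) == "low"

    def test_pass_is_mutually_exclusive(self):
        for mutant in range(1, 9):
            ac = annotate(somatic_call(), tumor_column(mutant), normal_column(30),
                          normal_column(30))
            if "PASS" in ac.flags:
                assert ac.flags == {"PASS"}


class TestGermlineDB:
    def _clean_germline(self, pos):
        t_col = make_column({"A": (10, 5), "G": (10, 5)}, pos=pos)
        n_col = make_column({"A": (10, 5), "G": (10, 5)}, pos=pos)
        return annotate(germline_call(pos=pos), t_col, n_col, n_col)

    def test_append_and_idempotence(self):
        db = GermlineDB()
        calls = [self._clean_germline(pos) for pos in (100, 200, 300)]
        update_germline_db(db, calls)
        assert len(db) == 3
        update_germline_db(db, calls)
        assert len(db) == 3

    def test_flagged_germline_not_appended(self):
        db = GermlineDB()
        thin_normal = make_column({"A": (3, 0), "G": (2, 0)})
        t_col = make_column({"A": (10, 5), "G": (10, 5)})
        ac = annotate(germline_call(), t_col, thin_normal, thin_normal)
        assert "SAN3" in ac.flags
        update_germline_db(db, [ac])
        assert len(db) == 0

    def test_round_trip_through_file(self, tmp_path):
        db = GermlineDB()
        db.add("chr1", 100, "A", "G")
        db.add("chr2", 5, "C", "T")
        db.add("chr1", 100, "A", "G")  # repeat observation increments count
        path = tmp_path / "germline.tsv"
        db.save(path)
        loaded = GermlineDB.load(path)
        assert len(loaded) == 2
        assert ("chr1", 100, "G") in loaded
        assert ("chr3", 1, "A") not in loaded
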