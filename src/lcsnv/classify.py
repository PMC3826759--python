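"""Joint germline/somatic classification of a tumor/normal genotype pair.

Classification follows a small rule table over the zygosity transition
between the matched normal and tumor genotypes.  With reference allele A
and variant G, the eight canonical cases are:

=======  ======  =================================  ==========
normal   tumor   detail                             class
=======  ======  =================================  ==========
Hom      Het     variant is the reference (G/G>A/G) Germline
Hom      Het     variant novel (A/A>A/G)            Somatic
Het      Hom     tumor allele in normal (A/G>G/G)   Germline
Het      Hom     tumor allele novel (A/G>T/T)       Somatic
Hom      Hom     same (G/G>G/G)                     Germline
Hom      Hom     different (A/A>G/G)                Somatic
Het      Het     same (A/G>A/G)                     Germline
Het      Het     different (A/G>T/G)                Somatic
=======  ======  =================================  ==========

A somatic call names the mutant allele: the tumor allele absent from the
normal genotype (for a Hom>Hom change, the tumor allele).  Transitions
consistent with loss of heterozygosity in the tumor — a heterozygote
collapsing onto one of its own alleles, or a homozygote gaining the
reference allele — carry a "possible-LOH" note; they remain classified
as above, since the caller does not model copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genotype import GenotypeCall

__all__ = ["JointCall", "NoCallError", "classify"]

GERMLINE = "Germline"
SOMATIC = "Somatic"


class NoCallError(ValueError):
    """Raised when either sample's genotype is a no-call."""


@dataclass
class JointCall:
    """Joint tumor/normal classification at one position."""

    chrom: str
    pos: int
    ref_base: str
    normal_gt: GenotypeCall
    tumor_gt: GenotypeCall
    classification: str                      # GERMLINE or SOMATIC
    mutant_allele: Optional[str] = None      # set for somatic calls
    notes: list[str] = field(default_factory=list)


def classify(
    normal_gt: GenotypeCall,
    tumor_gt: GenotypeCall,
    ref_base: str,
    chrom: str = ".",
    pos: int = 0,
) -> JointCall:
    """Classify one position from its normal and tumor genotypes.

    Raises :class:`NoCallError` if either genotype is a no-call; callers
    skip such positions with a logged reason.  When a heterozygous tumor
    differs from a heterozygous normal by two novel alleles, the
    first-ranked (higher-evidence) novel allele is reported as the mutant
    and the second is noted.
    """
    if not normal_gt.is_call or not tumor_gt.is_call:
        raise NoCallError(f"{chrom}:{pos}: genotype not callable in both samples")

    n_set = normal_gt.allele_set
    t_set = tumor_gt.allele_set
    notes: list[str] = []
    classification = GERMLINE
    mutant: Optional[str] = None

    if n_set == t_set and normal_gt.zygosity == tumor_gt.zygosity:
        classification = GERMLINE
    elif normal_gt.zygosity == "Hom" and tumor_gt.zygosity == "Het":
        novel = [a for a in tumor_gt.alleles if a not in n_set]
        if all(a == ref_base for a in novel):
            # tumor regained the reference next to a hom-variant normal;
            # consistent with LOH of the variant haplotype
            classification = GERMLINE
            notes.append("possible-LOH")
        else:
            classification = SOMATIC
            mutant = next(a for a in novel if a != ref_base)
    elif normal_gt.zygosity == "Het" and tumor_gt.zygosity == "Hom":
        t_allele = tumor_gt.alleles[0]
        if t_allele in n_set:
            classification = GERMLINE
            notes.append("possible-LOH")
        else:
            classification = SOMATIC
            mutant = t_allele
    elif normal_gt.zygosity == "Hom" and tumor_gt.zygosity == "Hom":
        classification = SOMATIC
        mutant = tumor_gt.alleles[0]
    else:  # Het -> Het with differing allele sets
        novel = [a for a in tumor_gt.alleles if a not in n_set]
        classification = SOMATIC
        mutant = novel[0]
        if len(novel) > 1:
            notes.append(f"second-novel-allele:{novel[1]}")

    return JointCall(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        normal_gt=normal_gt,
        tumor_gt=tumor_gt,
        classification=classification,
        mutant_allele=mutant,
        notes=notes,
    )
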