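"""Synthetic tumor/normal read-set generator with planted truth.

The generator emulates an exome-like tumor/normal pair from a diploid,
copy-number-neutral genome: germline variants (heterozygous at allele
fraction 1/2, homozygous at 1) are planted in both samples, somatic
variants only in the tumor, heterozygous in the tumor clone and diluted
by purity — a sample of purity p carries a somatic alt on an expected
fraction p/2 of its reads.  Reads are fixed-length, single-locus-
informative fragments: each read reports the bases and qualities it
contributes along the reference plus the attributes read filters need;
no full fragment model is simulated.

Sequencing errors substitute bases uniformly at a per-base rate.  A
fraction of reads is cloned into PCR duplicates sharing the source
read's start and strand.  Most clones are duplicate-marked, as a
duplicate-marking tool would do from coordinates and orientation; a
configurable fraction are *disguised*: left unmarked, with the mate
reassigned to a random other chromosome, emulating pairs whose mates hit
different copies of a homologous region so that coordinate-based marking
misses them.  Such reads still collapse under novel-start counting.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .reads import ReadRecord

__all__ = ["SimParams", "TruthVariant", "TruthSet", "simulate_pair",
           "simulate_reads", "make_truth", "disguised_duplicate_site"]

_BASES = "ACGT"
_OTHER = {b: [x for x in _BASES if x != b] for b in _BASES}


@dataclass(frozen=True)
class SimParams:
    """Generator settings.  Defaults mirror the mixture-series design:
    ~65x mean depth and 200 planted somatic variants; rates are typical
    short-read values."""

    purity: float = 1.0              # tumor DNA fraction
    mean_depth: float = 65.0         # reads per position
    n_somatic: int = 200
    n_germline_het: int = 60
    n_germline_hom: int = 30
    seq_error_rate: float = 0.002    # per base
    qual_mean: float = 35.0          # Phred
    qual_sd: float = 5.0
    dup_rate: float = 0.05           # fraction of reads cloned as duplicates
    disguised_dup_rate: float = 0.1  # fraction of clones left unmarked
    region_length: int = 15_000
    read_len: int = 50
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("purity", "seq_error_rate", "dup_rate", "disguised_dup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0 or self.region_length <= 0 or self.read_len <= 0:
            raise ValueError("depths and lengths must be positive")


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                # "somatic" | "germline-het" | "germline-hom"
    expected_tumor_vaf: float


@dataclass(frozen=True)
class TruthSet:
    """Planted variants plus the reference they were planted into."""

    chrom: str
    region_length: int
    reference: str
    variants: tuple[TruthVariant, ...]

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, 1, self.region_length)

    def somatic_positions(self) -> dict[int, str]:
        return {v.pos: v.alt for v in self.variants if v.kind == "somatic"}


def _truth_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 101])


def make_truth(params: SimParams) -> TruthSet:
    """Draw the reference sequence and plant variant positions.

    Independent of purity and of the read-sampling streams, so one seed
    defines one shared truth across a purity series.  Variant positions
    keep one read-length clear of the region edges so nominal depth
    applies at every planted site.
    """
    rng = _truth_rng(params.seed)
    ref = "".join(rng.choice(list(_BASES), size=params.region_length))
    n_total = params.n_somatic + params.n_germline_het + params.n_germline_hom
    lo = params.read_len + 1
    hi = params.region_length - params.read_len
    if hi - lo + 1 < n_total:
        raise ValueError("region too short for requested variant count")
    positions = rng.choice(np.arange(lo, hi + 1), size=n_total, replace=False)
    positions.sort()
    kinds = (
        ["somatic"] * params.n_somatic
        + ["germline-het"] * params.n_germline_het
        + ["germline-hom"] * params.n_germline_hom
    )
    rng.shuffle(kinds)
    variants = []
    for pos, kind in zip(positions, kinds):
        ref_base = ref[pos - 1]
        alt = _OTHER[ref_base][rng.integers(0, 3)]
        vaf = {
            "somatic": params.purity / 2.0,
            "germline-het": 0.5,
            "germline-hom": 1.0,
        }[kind]
        variants.append(
            TruthVariant(params.chrom, int(pos), ref_base, alt, kind, vaf)
        )
    return TruthSet(
        chrom=params.chrom,
        region_length=params.region_length,
        reference=ref,
        variants=tuple(variants),
    )


def simulate_reads(
    params: SimParams,
    truth: TruthSet,
    sample: str,
    stream: int,
) -> list[ReadRecord]:
    """Generate one sample's reads against ``truth``.

    ``sample`` is "tumor" or "normal": the normal never carries somatic
    alts (they can still appear via sequencing error).  ``stream``
    separates the tumor and normal random streams under one seed.
    """
    if sample not in ("tumor", "normal"):
        raise ValueError("sample must be 'tumor' or 'normal'")
    p = params
    rng = np.random.default_rng([p.seed, 211, stream])
    pyrng = random.Random(int(rng.integers(0, 2**31)))
    ref = truth.reference
    L = p.region_length
    rl = p.read_len

    var_pos = np.array([v.pos for v in truth.variants], dtype=np.int64)
    var_alt = [v.alt for v in truth.variants]

    def _allele_fraction(kind: str) -> float:
        if kind == "somatic":
            # heterozygous in the tumor clone, diluted by purity; absent
            # from the matched normal
            return 0.0 if sample == "normal" else p.purity / 2.0
        return 0.5 if kind == "germline-het" else 1.0

    var_p = np.array([_allele_fraction(v.kind) for v in truth.variants])

    n_reads = int(round(L * p.mean_depth / rl))
    starts = rng.integers(1, L - rl + 2, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    quals = np.clip(
        np.rint(rng.normal(p.qual_mean, p.qual_sd, size=(n_reads, rl))), 2, 41
    ).astype(np.int64)
    err_mask = rng.random((n_reads, rl)) < p.seq_error_rate
    err_rows = err_mask.any(axis=1)

    dup_chroms = [f"chr{i}" for i in range(2, 10)]
    out: list[ReadRecord] = []
    for i in range(n_reads):
        start = int(starts[i])
        strand = "+" if strands[i] else "-"
        template = list(ref[start - 1 : start - 1 + rl])
        # plant variant alleles this molecule carries
        j0 = int(np.searchsorted(var_pos, start))
        j1 = int(np.searchsorted(var_pos, start + rl - 1, side="right"))
        for j in range(j0, j1):
            pv = var_p[j]
            if pv >= 1.0 or (pv > 0.0 and pyrng.random() < pv):
                template[int(var_pos[j]) - start] = var_alt[j]
        molecule = template  # pre-error bases shared by PCR duplicates

        def finish(seq_list, qrow, *, dup: bool, disguised: bool) -> ReadRecord:
            mm = sum(1 for k in range(rl) if seq_list[k] != ref[start - 1 + k])
            if disguised:
                mate_chrom = pyrng.choice(dup_chroms)
                mate_start = pyrng.randint(1, 10_000_000)
            else:
                mate_chrom = p.chrom
                mate_start = min(start + 3 * rl, L)
            return ReadRecord(
                chrom=p.chrom,
                start=start,
                strand=strand,
                seq="".join(seq_list),
                quals=tuple(qrow),
                mapq_single=60,
                align_len=rl,
                mismatches=mm,
                is_duplicate=dup,
                is_proper_pair=not disguised,
                is_second_in_pair=False,
                mate_chrom=mate_chrom,
                mate_start=mate_start,
            )

        seq = list(molecule)
        if err_rows[i]:
            for k in np.nonzero(err_mask[i])[0]:
                seq[k] = _OTHER[seq[k]][pyrng.randint(0, 2)]
        out.append(finish(seq, quals[i].tolist(), dup=False, disguised=False))

        if pyrng.random() < p.dup_rate:
            # PCR clone: same molecule, fresh errors and qualities
            cseq = list(molecule)
            for k in range(rl):
                if pyrng.random() < p.seq_error_rate:
                    cseq[k] = _OTHER[cseq[k]][pyrng.randint(0, 2)]
            cq = [
                min(41, max(2, int(round(pyrng.gauss(p.qual_mean, p.qual_sd)))))
                for _ in range(rl)
            ]
            disguised = pyrng.random() < p.disguised_dup_rate
            out.append(finish(cseq, cq, dup=not disguised, disguised=disguised))
    return out


def simulate_pair(
    params: SimParams,
    truth: Optional[TruthSet] = None,
) -> tuple[list[ReadRecord], list[ReadRecord], TruthSet]:
    """Generate a matched tumor/normal pair plus its truth set.

    The truth (reference and planted variants) depends only on the seed
    and variant counts, not on purity, so calling this across a purity
    series with one seed reuses one shared truth; the normal sample's
    reads are likewise purity-independent.
    """
    if truth is None:
        truth = make_truth(params)
    tumor = simulate_reads(params, truth, "tumor", stream=1)
    normal = simulate_reads(params, truth, "normal", stream=2)
    return tumor, normal, truth


def disguised_duplicate_site(
    seed: int = 0,
    n_disguised: int = 6,
    n_starts: int = 2,
    depth: int = 30,
) -> tuple[list[ReadRecord], list[ReadRecord], TruthSet, int, str]:
    """Build a fixture where a false variant rests on disguised duplicates.

    Returns (tumor_reads, normal_reads, truth, pos, alt): at ``pos`` the
    tumor carries ``n_disguised`` unmarked duplicate reads supporting a
    non-reference allele but collapsing onto ``n_starts`` distinct
    (strand, start) keys — the pattern left behind when mates map to
    different homologous loci and defeat coordinate-based duplicate
    marking.  All other coverage is clean reference.
    """
    params = SimParams(
        purity=1.0,
        mean_depth=depth,
        n_somatic=0,
        n_germline_het=0,
        n_germline_hom=0,
        region_length=2_000,
        seed=seed,
    )
    truth = make_truth(params)
    tumor = simulate_reads(params, truth, "tumor", stream=1)
    normal = simulate_reads(params, truth, "normal", stream=2)

    pyrng = random.Random(seed + 7)
    rl = params.read_len
    pos = params.region_length // 2
    ref_base = truth.reference[pos - 1]
    alt = _OTHER[ref_base][0]
    starts = [pos - rl + 1 + 5 * k for k in range(n_starts)]
    dup_chroms = [f"chr{i}" for i in range(2, 10)]
    for n in range(n_disguised):
        start = starts[n % n_starts]
        seq = list(truth.reference[start - 1 : start - 1 + rl])
        seq[pos - start] = alt
        tumor.append(
            ReadRecord(
                chrom=params.chrom,
                start=start,
                strand="+",
                seq="".join(seq),
                quals=tuple([35] * rl),
                mapq_single=60,
                align_len=rl,
                mismatches=1,
                is_duplicate=False,
                is_proper_pair=False,
                is_second_in_pair=False,
                mate_chrom=pyrng.choice(dup_chroms),
                mate_start=pyrng.randint(1, 10_000_000),
            )
        )
    return tumor, normal, truth, pos, alt
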