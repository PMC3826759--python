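# Methods

## Model and procedure

`lcsnv` implements heuristic somatic point-mutation calling on a
matched tumor/normal pair. The unit of analysis is the pileup column:
per position and sample, forward/reverse read counts per allele, the
sum of Phred base qualities per allele, and the set of distinct
(strand, 5′ start) keys supporting each allele. Three pileups are
built per run — filtered tumor, filtered normal, and an unfiltered
non-duplicate normal used only to re-check somatic candidates for any
trace of the variant.

Genotypes are called per sample by coverage-banded minimum-evidence
rules rather than likelihoods. An allele is supported when its read
count meets the band minimum (3 at ≤ 20×; 4 at 21–50×; above 50×, 5%
of reads on one strand or 2.5% on two, with an unconditional floor of
3) **and** its summed base quality is at least 10% of the column total
(5% when on both strands above 50×). The two most common alleles are
tested; two passes give a heterozygote, one a homozygote. The pair of
genotypes is then classified germline or somatic by the rule table in
`classify.py`, and the call is annotated with the post-processing flags
(`annotate.py`), from which the confidence tier follows mechanically:
PASS→high, COVN12-only→medium, else low.

The design trades calibrated uncertainty for sensitivity at low tumor
purity: a heterozygous somatic variant in a diploid, copy-neutral
tumor diluted to purity *p* has expected VAF *p*/2, and at 65× and
*p* = 0.1 that is ~3 mutant reads — exactly the trigger floor. No
p-value is computed or reported (VCF QUAL is `.`).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band minima (`min_reads_low/mid`) | 3 / 4 | reads | the evidence trigger and its > 20× tightening |
| fraction floors | 5% / 2.5% | of reads | > 50× replacement for absolute counts |
| quality fractions | 10% / 5% | of summed Phred | guards against low-quality pileup noise |
| `min_mutant_reads` (MR) | 5 | reads | PASS requirement; below it calls are low confidence |
| `min_novel_starts` (NNS) | 4 | distinct (strand, 5′ start) keys | proxies independent source molecules |
| `min_normal_coverage_somatic` (COVN12) | 12 | reads | below it a "somatic" call may be an under-sampled germline het |
| SBIAS gates | 5 variant reads one-sided, ≥ 5 reads opposite strand | reads | bias is only informative when the opposite strand was sampled; applied to Illumina data only |

All are overridable through the `[thresholds]` section of the INI
configuration.

Interpretation choices where the rules leave room:

* "over 20×"/"above 50×" are strict inequalities; coverage 20 uses the
  3-read rule and coverage 50 the 4-read rule (boundary tests pin this).
* In the > 50× band the fractional rules replace the absolute count
  but the global 3-read floor still applies: 2.5% of 51 reads would
  otherwise admit a 2-read call, contradicting the unconditional
  trigger.
* The quality fraction is Σ(variant base qualities) / Σ(all base
  qualities) in the column.
* Two-most-common-allele ties break by count, then summed quality,
  then alphabetical base — determinism only.
* If no allele passes evidence, the position is called homozygous
  reference when the reference base is observed, else a no-call; joint
  classification skips positions that are a no-call in either sample.
* The novel-start key is (strand, 5′-most aligned position): reads
  amplified from one molecule share their 5′ end regardless of where
  their mates map.
* MIN/MIUN trigger on a single mutant-allele read in the respective
  normal pileup — the most conservative reading of "also found".
* MR counts raw filtered mutant reads; NNS counts deduplicated start
  keys; they are independent checks.
* Germline-side checks (SAN3/SAT3, MR/NNS) evaluate the non-reference
  allele of the genotype, with tumor-sample counts for MR/NNS.
* Germline-database export ("high quality") means a germline call with
  zero flags; lookups match (chrom, pos, alt) exactly, with no patient
  identity modeled.
* The possible-LOH note attaches to the two rule-table rows consistent
  with allele loss (Het→Hom onto an own allele, Hom→Het regaining the
  reference); the companion check-normal-coverage concern is realized
  as the COVN12 flag rather than a classification change.

Degenerate inputs: bases called N or with quality 0 carry no evidence
and are excluded from counts *and* coverage; deletions spanning a
position contribute nothing; empty columns are no-calls; zero
denominators in metrics return 0 with a warning.

## The synthetic generator

`simulate.py` emulates an exome-like pair: a uniform-random reference
region (default 15 kb), planted somatic (default 200), germline-het
(60) and germline-hom (30) variants, fixed-length 50 bp
single-locus-informative reads with uniform starts (per-position depth
is then approximately Poisson at the 65× default), Gaussian Phred
qualities (mean 35, sd 5, clipped to [2, 41]), uniform substitution
errors at 2×10⁻³ per base, and PCR duplicates: 5% of reads are cloned
(same molecule, fresh errors/qualities), of which 10% are *disguised* —
left unmarked with the mate reassigned to a random other chromosome,
reproducing the failure mode of coordinate-based duplicate marking at
homologous loci. Somatic alleles enter tumor reads at probability
purity/2; the truth set and the normal sample depend only on the seed,
so a purity series shares one truth. Everything is deterministic under
the seed (numpy Generator plus a derived `random.Random` stream).

What it does **not** model: coverage heterogeneity and capture bias,
mapping error, indels and copy-number change, subclonality, phased
haplotypes, base-quality error correlation. Consequently simulated
sensitivities at a given nominal purity exceed those measured on real
capture data, and benchmark assertions are therefore about *monotone
decay* of sensitivity with purity (and non-decrease with depth), not
about absolute decay values. The mixture-series design — purity levels
{0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0} at 65× mean depth — mirrors the
motivating dilution experiment at desk scale; 15 kb × 65× keeps a full
six-purity, ten-seed series around a minute and a half on one CPU,
which is the problem size the acceptance property uses.

## Numerical and format choices

Coordinates are 1-based fully closed throughout (VCF convention);
pysam's 0-based records are converted at the boundary. The read-filter
DSL is a deliberately small recursive-descent grammar (comparisons,
flag atoms, and/or/not, parentheses) with position-reporting errors;
the SOLiD and Illumina presets are expressed in it, and mismatch counts
are taken as precomputed per-read integers (no color-space handling).
VCF output is dialect 4.1 with flags in FILTER and NNS/MR duplicated in
INFO; the DCC table is a declared, versioned column set approximating
the ICGC simple-somatic-mutation open tier. Output is byte-deterministic
modulo the dated header line, which `--no-date` suppresses.

## Known limitations

Single-region, two-sample, SNV-only; no realignment or recalibration;
multi-allelic sites reduce to the top two alleles (a het-to-het change
with two novel tumor alleles reports the better-supported one and notes
the second); the whole-genome-scale post-filters for repeat/low-
complexity/near-indel context are out of scope.
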