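"""Purity-mixture benchmark harness, verification rules, and metrics.

``run_mixture_series`` emulates the controlled-mixture experiment: one
shared truth set, one matched normal, and a tumor re-sequenced at each
purity level; the full caller runs per mixture and PASS somatic calls
are scored against the planted truth.

The two verification rules mirror the orthogonal-platform criteria used
to label calls true or false:

* amplicon deep sequencing: verified iff tumor and normal are both
  covered to at least 100 reads, the mutant allele is at >= 10% in the
  tumor, and at < 0.5% in the normal;
* cross-platform re-sequencing: verified iff depth >= 20, mutant allele
  fraction >= 5%, and at least 3 variant reads on the other platform.

Metrics are precision TP/(TP+FP) and sensitivity TP/(TP+FN).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import AnnotatedCall
from .caller import call_from_pileups
from .filters import PRESETS, FilterSpec
from .pileup import PileupColumn, build_pileup
from .simulate import SimParams, TruthSet, make_truth, simulate_reads

__all__ = [
    "verify_amplicon",
    "verify_cross_platform",
    "Metrics",
    "score_counts",
    "score_calls",
    "overlap_report",
    "run_mixture_series",
]

VERIFIED = "verified"
NOT_VERIFIED = "not_verified"

# amplicon verification criteria
AMPLICON_MIN_DEPTH = 100
AMPLICON_MIN_TUMOR_FRACTION = 0.10
AMPLICON_MAX_NORMAL_FRACTION = 0.005  # strict: normal fraction must be below

# cross-platform verification criteria
XPLAT_MIN_DEPTH = 20
XPLAT_MIN_FRACTION = 0.05
XPLAT_MIN_READS = 3


def verify_amplicon(
    tumor_col: PileupColumn, normal_col: PileupColumn, alt: str
) -> str:
    """Deep-amplicon verification of one candidate somatic position."""
    t_cov = tumor_col.coverage
    n_cov = normal_col.coverage
    if t_cov < AMPLICON_MIN_DEPTH or n_cov < AMPLICON_MIN_DEPTH:
        return NOT_VERIFIED
    if tumor_col.count(alt) / t_cov < AMPLICON_MIN_TUMOR_FRACTION:
        return NOT_VERIFIED
    if normal_col.count(alt) / n_cov >= AMPLICON_MAX_NORMAL_FRACTION:
        return NOT_VERIFIED
    return VERIFIED


def verify_cross_platform(alt_col: PileupColumn, alt: str) -> str:
    """Verification against a pileup from an alternate sequencing platform."""
    cov = alt_col.coverage
    count = alt_col.count(alt)
    if cov < XPLAT_MIN_DEPTH:
        return NOT_VERIFIED
    if count < XPLAT_MIN_READS:
        return NOT_VERIFIED
    if count / cov < XPLAT_MIN_FRACTION:
        return NOT_VERIFIED
    return VERIFIED


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("precision undefined (TP+FP=0); reporting 0")
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("sensitivity undefined (TP+FN=0); reporting 0")
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def precision_pct(self) -> int:
        return round(100 * self.precision)

    @property
    def sensitivity_pct(self) -> int:
        return round(100 * self.sensitivity)


def score_counts(tp: int, fp: int, fn: int) -> Metrics:
    """Metrics from raw outcome counts."""
    return Metrics(tp=tp, fp=fp, fn=fn)


def score_calls(
    called: Iterable,
    truth: Iterable,
) -> Metrics:
    """Metrics from a called set against a truth/verification label set.

    Elements are compared by equality; (chrom, pos, alt) tuples are the
    usual keys.
    """
    called_set = set(called)
    truth_set = set(truth)
    tp = len(called_set & truth_set)
    return Metrics(tp=tp, fp=len(called_set - truth_set), fn=len(truth_set - called_set))


def overlap_report(call_sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of named call sets.

    Keys are sorted tuples of set names; the value counts items present
    in exactly those sets and no others.
    """
    names = sorted(call_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 call sets")
    sets = {n: set(call_sets[n]) for n in names}
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            out[combo] = len(inside - outside)
    return out


def run_mixture_series(
    purities: Sequence[float],
    base_params: SimParams,
    platform: str = "illumina",
    filter_spec: Optional[FilterSpec] = None,
) -> pd.DataFrame:
    """Run the caller across a tumor-purity dilution series.

    One truth set and one matched normal (from ``base_params.seed``) are
    shared by every mixture; the tumor is re-simulated per purity.  A
    true positive is a PASS somatic call at a planted somatic site with
    the planted alt; a false positive is any other PASS somatic call.

    Returns a DataFrame with one row per purity: n_truth, detected_pass,
    sensitivity, false_positives.
    """
    if len(purities) < 2:
        raise ValueError("need at least 2 purity levels")
    if filter_spec is None:
        filter_spec = PRESETS[platform]

    truth = make_truth(base_params)
    region = truth.region
    normal_reads = simulate_reads(base_params, truth, "normal", stream=2)
    normal_pile = build_pileup(normal_reads, region, filter_spec, truth.reference)
    normal_unf_pile = build_pileup(normal_reads, region, None, truth.reference)
    truth_keys = {
        (v.chrom, v.pos, v.alt) for v in truth.variants if v.kind == "somatic"
    }

    rows = []
    for purity in purities:
        params = replace(base_params, purity=purity)
        tumor_reads = simulate_reads(params, truth, "tumor", stream=1)
        tumor_pile = build_pileup(tumor_reads, region, filter_spec, truth.reference)
        calls = call_from_pileups(
            tumor_pile, normal_pile, normal_unf_pile, region, platform=platform
        )
        pass_somatic = {
            (c.call.chrom, c.call.pos, c.call.mutant_allele)
            for c in calls
            if c.is_somatic and c.flags == {"PASS"}
        }
        m = score_calls(pass_somatic, truth_keys)
        rows.append(
            {
                "purity": purity,
                "n_truth": len(truth_keys),
                "detected_pass": m.tp,
                "sensitivity": m.sensitivity if truth_keys else 0.0,
                "false_positives": m.fp,
            }
        )
    return pd.DataFrame(rows)
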