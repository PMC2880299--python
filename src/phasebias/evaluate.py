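"""Comparison of phased output against phase-known truth.

Implements the error taxonomy for confidently-resolved-but-wrong haplotype
pairs, the accounting of unresolved (below-threshold) genotypes, the detection
of alleles lost when unresolved individuals are omitted, the genotypic
configurations (allele-frequency profiles) of unresolved genotypes, and the
divergence skew of lost alleles relative to the dataset mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from phasebias.popgen import p_distance_matrix
from phasebias.phasing import ThresholdedResult
from phasebias.simulate import TruthDataset

__all__ = [
    "ErrorClass",
    "EvalSummary",
    "ConfigRecord",
    "DivergenceSkew",
    "classify_error",
    "evaluate_dataset",
    "find_lost_alleles",
    "configuration_profile",
    "divergence_skew",
    "het_error_relationship",
    "pooled_error_rate",
]


class ErrorClass(Enum):
    """Taxonomy of haplotype-pair reconstruction outcomes.

    Each inferred haplotype is either correct (a member of the true pair),
    misidentified (a different allele that exists in the phase-known dataset),
    or novel (a sequence absent from the phase-known dataset).  NOV_NOV closes
    the classification: the four mixed/mis categories cover every mistake a
    complement-consistent phaser can make, but externally supplied pairs may
    be inconsistent.
    """

    CORRECT = "correct"
    E_COR_NOV = "E_COR+NOV"
    E_COR_MIS = "E_COR+MIS"
    E_MIS_MIS = "E_MIS+MIS"
    E_MIS_NOV = "E_MIS+NOV"
    E_NOV_NOV = "E_NOV+NOV"


def classify_error(
    true_pair: Sequence[str],
    inferred_pair: Sequence[str],
    known_alleles: Iterable[str],
) -> ErrorClass:
    """Classify one inferred haplotype pair against the truth.

    ``known_alleles`` is the set of distinct allele sequences present in the
    original phase-known dataset.  Pairs are unordered; the comparison is a
    multiset match, so a correctly recovered homozygote-like duplicate counts
    once per copy.
    """
    ta, tb = true_pair
    ia, ib = inferred_pair
    if len({len(ta), len(tb), len(ia), len(ib)}) > 1:
        raise ValueError("haplotypes differ in length")
    truth = Counter((ta, tb))
    inferred = Counter((ia, ib))
    if truth == inferred:
        return ErrorClass.CORRECT
    known = set(known_alleles)
    remaining = truth.copy()
    labels = []
    for hap in (ia, ib):
        if remaining[hap] > 0:
            labels.append("cor")
            remaining[hap] -= 1
        elif hap in known:
            labels.append("mis")
        else:
            labels.append("nov")
    pair = tuple(sorted(labels))
    return {
        ("cor", "nov"): ErrorClass.E_COR_NOV,
        ("cor", "mis"): ErrorClass.E_COR_MIS,
        ("mis", "mis"): ErrorClass.E_MIS_MIS,
        ("mis", "nov"): ErrorClass.E_MIS_NOV,
        ("nov", "nov"): ErrorClass.E_NOV_NOV,
        ("cor", "cor"): ErrorClass.E_COR_MIS,  # duplicate of one true hap
    }[pair]


@dataclass
class EvalSummary:
    """Per-dataset, per-threshold accounting of phasing outcomes.

    N_ERR counts above-threshold (confidently resolved) individuals whose best
    pair differs from truth; N_LCP counts below-threshold individuals, split
    into correctly and incorrectly inferred.  Error-class tallies are kept
    separately for the N_ERR and N_LCP-incorrect pools.
    """

    threshold: float
    n_ambiguous: int
    n_err: int
    n_lcp: int
    n_lcp_correct: int
    n_lcp_incorrect: int
    n_lost: int
    lost_alleles: tuple[str, ...]
    err_classes: dict[ErrorClass, int]
    lcp_incorrect_classes: dict[ErrorClass, int]

    @property
    def proportion_unresolved(self) -> Optional[float]:
        return self.n_lcp / self.n_ambiguous if self.n_ambiguous else None


def find_lost_alleles(
    truth: TruthDataset, unresolved_ids: Iterable[str]
) -> tuple[int, list[str]]:
    """Distinct alleles whose every copy sits in an unresolved individual.

    These gene lineages vanish from the dataset when unresolved genotypes are
    omitted.  Returns (N_LOST, list of lost allele sequences).
    """
    unresolved = set(unresolved_ids)
    ids = {ind.individual_id for ind in truth.individuals}
    if not unresolved <= ids:
        raise ValueError("unresolved ids not a subset of the dataset's individuals")
    lookup = dict(zip(truth.alignment.ids, truth.alignment.sequences))
    carriers: dict[str, set[str]] = {}
    for ind in truth.individuals:
        for allele_id in (ind.allele_a, ind.allele_b):
            carriers.setdefault(lookup[allele_id], set()).add(ind.individual_id)
    lost = sorted(
        seq for seq, inds in carriers.items() if inds and inds <= unresolved
    )
    return len(lost), lost


def evaluate_dataset(
    truth: TruthDataset, thresholded: ThresholdedResult
) -> EvalSummary:
    """Score a thresholded phasing result against the phase-known truth."""
    known = set(truth.alignment.sequences)
    truth_ids = {g.individual_id for g in truth.genotypes if g.is_ambiguous}
    seen = set(thresholded.resolved) | set(thresholded.unresolved)
    if not seen <= {i.individual_id for i in truth.individuals}:
        raise ValueError("phased individual absent from the truth dataset")

    n_err = 0
    err_classes: Counter = Counter()
    for ind_id, post in thresholded.resolved.items():
        cls = classify_error(truth.true_pair(ind_id), post.best_pair, known)
        if cls is not ErrorClass.CORRECT:
            n_err += 1
            err_classes[cls] += 1

    n_lcp_correct = 0
    lcp_classes: Counter = Counter()
    for ind_id, post in thresholded.unresolved.items():
        cls = classify_error(truth.true_pair(ind_id), post.best_pair, known)
        if cls is ErrorClass.CORRECT:
            n_lcp_correct += 1
        else:
            lcp_classes[cls] += 1
    n_lcp = len(thresholded.unresolved)

    n_lost, lost = find_lost_alleles(truth, thresholded.unresolved_ids)
    return EvalSummary(
        threshold=thresholded.threshold,
        n_ambiguous=len(truth_ids),
        n_err=n_err,
        n_lcp=n_lcp,
        n_lcp_correct=n_lcp_correct,
        n_lcp_incorrect=n_lcp - n_lcp_correct,
        n_lost=n_lost,
        lost_alleles=tuple(lost),
        err_classes=dict(err_classes),
        lcp_incorrect_classes=dict(lcp_classes),
    )


@dataclass
class ConfigRecord:
    """Allele-frequency configuration of one unresolved genotype.

    Frequencies are population frequencies among all 2N allele copies of the
    full dataset; ``common >= rare``.  "Singleton" means exactly one copy
    among 2N; "rare" means frequency < 0.05.
    """

    individual_id: str
    common_freq: float
    rare_freq: float
    rare_is_singleton: bool
    both_rare: bool


def configuration_profile(
    truth: TruthDataset, unresolved_ids: Iterable[str]
) -> list[ConfigRecord]:
    """Per-unresolved-genotype constituent-allele frequencies and rarity flags."""
    lookup = dict(zip(truth.alignment.ids, truth.alignment.sequences))
    freqs = Counter(truth.alignment.sequences)
    two_n = len(truth.alignment.sequences)
    records = []
    by_id = {ind.individual_id: ind for ind in truth.individuals}
    for ind_id in sorted(set(unresolved_ids)):
        ind = by_id[ind_id]
        fa = freqs[lookup[ind.allele_a]] / two_n
        fb = freqs[lookup[ind.allele_b]] / two_n
        common, rare = max(fa, fb), min(fa, fb)
        records.append(
            ConfigRecord(
                individual_id=ind_id,
                common_freq=common,
                rare_freq=rare,
                rare_is_singleton=round(rare * two_n) == 1,
                both_rare=common < 0.05,
            )
        )
    return records


@dataclass
class DivergenceSkew:
    """Pairwise-divergence skew of the alleles lost from one dataset.

    ``p_lost`` holds, per lost allele, the mean uncorrected p-distance from
    that allele to every other distinct allele; ``p_dataset`` is the mean over
    all pairwise comparisons among distinct alleles.  ``difference`` is the
    dataset's single signed data point: sum(p_lost) - p_dataset, positive when
    lost alleles are more divergent than average.
    """

    p_lost: tuple[float, ...]
    p_dataset: float
    difference: float


def divergence_skew(
    truth: TruthDataset, lost_alleles: Sequence[str]
) -> Optional[DivergenceSkew]:
    """Divergence skew of lost alleles; ``None`` when nothing was lost."""
    if not lost_alleles:
        return None
    distinct = sorted(set(truth.alignment.sequences))
    if len(distinct) < 2:
        raise ValueError("need at least two distinct alleles")
    d = p_distance_matrix(distinct)
    idx = {seq: i for i, seq in enumerate(distinct)}
    n = len(distinct)
    off_diag_mean = d.sum() / (n * (n - 1))
    p_lost = []
    for seq in lost_alleles:
        i = idx[seq]
        p_lost.append(float((d[i].sum()) / (n - 1)))
    return DivergenceSkew(
        p_lost=tuple(p_lost),
        p_dataset=float(off_diag_mean),
        difference=float(sum(p_lost) - off_diag_mean),
    )


def het_error_relationship(
    records: Sequence[tuple[int, bool]]
) -> Optional[float]:
    """Correlation between heterozygous-site count and phasing error.

    ``records`` pairs each ambiguous genotype's heterozygous-site count with
    an error indicator (N_ERR or N_LCP-incorrect membership).  Genotypes are
    pooled by het-site class and the Pearson correlation between the class
    value and the per-class error proportion is returned; ``None`` when fewer
    than three classes exist or either margin has zero variance.
    """
    by_class: dict[int, list[bool]] = {}
    for h, err in records:
        by_class.setdefault(h, []).append(err)
    if len(by_class) < 3:
        return None
    xs = sorted(by_class)
    ys = [float(np.mean(by_class[x])) for x in xs]
    if len(set(ys)) == 1:
        return None
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def pooled_error_rate(n_errors: int, n_ambiguous: int) -> float:
    """Pooled false-positive rate as a percentage (errors per ambiguous genotype)."""
    if n_ambiguous <= 0:
        raise ValueError("no ambiguous genotypes")
    if n_errors < 0 or n_errors > n_ambiguous:
        raise ValueError("error count out of range")
    return 100.0 * n_errors / n_ambiguous
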