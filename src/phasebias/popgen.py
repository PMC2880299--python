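"""Polymorphism summaries and neutrality statistics for population sequence samples.

All statistics operate on an aligned sample of haploid sequences (strings over
an arbitrary character alphabet; indel-recoded columns are treated as ordinary
characters).  Diploid-level summaries (G_N, H_O) additionally need the pairing
of allele copies into individuals.

Statistics that are undefined for a sample (Tajima's D with no segregating
sites, Fu's F_S for a monomorphic or single-haplotype sample) are reported as
``None``, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PopGenSummary",
    "count_segregating_sites",
    "count_distinct_alleles",
    "watterson_theta",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "tajimas_d",
    "fus_fs",
    "ewens_k_distribution",
    "p_distance_matrix",
    "summarize_polymorphism",
]


def _check_alignment(seqs: Sequence[str]) -> int:
    if not seqs:
        raise ValueError("empty sequence sample")
    length = len(seqs[0])
    for s in seqs:
        if len(s) != length:
            raise ValueError("sequences differ in length")
    return length


def _as_matrix(seqs: Sequence[str]) -> np.ndarray:
    """View an alignment as an (n, L) byte matrix."""
    _check_alignment(seqs)
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def count_segregating_sites(seqs: Sequence[str]) -> int:
    """Number of alignment columns with two or more states (S).

    Columns with three or more states count once: S counts segregating sites,
    not mutations.
    """
    mat = _as_matrix(seqs)
    return int((mat != mat[0]).any(axis=0).sum())


def count_distinct_alleles(seqs: Sequence[str]) -> int:
    """Number of distinct sequences in the sample (A_N)."""
    _check_alignment(seqs)
    return len(set(seqs))


def harmonic_number(m: int) -> float:
    return float(sum(1.0 / i for i in range(1, m + 1)))


def watterson_theta(s: int, n: int, length: int) -> tuple[float, float]:
    """Watterson's segregating-sites estimator of theta.

    Returns ``(theta_locus, theta_site)`` where ``theta_locus = S / a1`` with
    ``a1`` the (n-1)-th harmonic number, and ``theta_site`` the per-site value.
    """
    if n < 2:
        raise ValueError("need at least two sequences")
    if length < 1:
        raise ValueError("length must be positive")
    if s < 0:
        raise ValueError("negative segregating-site count")
    a1 = harmonic_number(n - 1)
    theta_locus = s / a1
    return theta_locus, theta_locus / length


def _pairwise_difference_total(mat: np.ndarray) -> float:
    """Sum of pairwise nucleotide differences over all C(n,2) sequence pairs.

    Computed column-wise from state counts: a column with state counts c_i
    contributes C(n,2) - sum_i C(c_i,2) mismatching pairs.
    """
    n = mat.shape[0]
    total_pairs = n * (n - 1) / 2
    diff = 0.0
    for col in mat.T:
        _, counts = np.unique(col, return_counts=True)
        same = (counts * (counts - 1) / 2).sum()
        diff += total_pairs - same
    return float(diff)


def mean_pairwise_differences(seqs: Sequence[str]) -> float:
    """Mean number of pairwise differences per locus (k-hat)."""
    mat = _as_matrix(seqs)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    return _pairwise_difference_total(mat) / (n * (n - 1) / 2)


def nucleotide_diversity(seqs: Sequence[str]) -> tuple[float, float]:
    """Nei's nucleotide diversity pi, per locus and per site."""
    pi_locus = mean_pairwise_differences(seqs)
    return pi_locus, pi_locus / len(seqs[0])


def tajimas_d(seqs: Sequence[str]) -> Optional[float]:
    """Tajima's D: normalized difference between pi- and S-based theta estimates.

    Returns ``None`` when the sample has no segregating sites or when the
    variance term vanishes (n = 2, where pi and theta_W coincide by
    construction): the statistic is undefined, not zero.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    s = count_segregating_sites(seqs)
    if s == 0:
        return None
    khat = mean_pairwise_differences(seqs)
    a1 = harmonic_number(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    return (khat - s / a1) / math.sqrt(var)


def _log_stirling_first_unsigned(n: int) -> list[float]:
    """log |s(n, k)| for k = 0..n via the triangular recurrence.

    Exact integer arithmetic (Python bigints) keeps the recurrence stable for
    the sample sizes used here (n <= a few hundred); logs are taken at the end.
    """
    row = [0, 1]  # n = 1: s(1,0)=0, s(1,1)=1
    for m in range(1, n):
        new = [0] * (m + 2)
        for k in range(1, m + 2):
            new[k] = m * row[k] + row[k - 1] if k <= m else row[k - 1]
        row = new
    return [math.log(v) if v > 0 else -math.inf for v in row]


def ewens_k_distribution(theta: float, n: int) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling distribution.

    P(K=k) = |s(n,k)| theta^k / theta^(n), with |s| the unsigned Stirling
    numbers of the first kind and theta^(n) the rising factorial.  Evaluated
    in log space.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n < 1:
        raise ValueError("n must be positive")
    log_s = _log_stirling_first_unsigned(n)
    log_rising = float(sum(math.log(theta + i) for i in range(n)))
    log_theta = math.log(theta)
    logp = np.array(
        [log_s[k] + k * log_theta - log_rising for k in range(1, n + 1)]
    )
    return np.exp(logp)


def fus_fs(seqs: Sequence[str]) -> Optional[float]:
    """Fu's F_S statistic.

    With theta set to the mean pairwise difference k-hat, S' is the Ewens
    probability of observing at least the sampled number of distinct
    haplotypes; F_S = ln(S' / (1 - S')).  Undefined (``None``) when k-hat is
    zero or when S' reaches 0 or 1 exactly (k_obs = 1 gives S' = 1).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    khat = mean_pairwise_differences(seqs)
    if khat == 0:
        return None
    k_obs = count_distinct_alleles(seqs)
    probs = ewens_k_distribution(khat, n)
    s_prime = float(probs[k_obs - 1 :].sum())
    if s_prime >= 1.0 or s_prime <= 0.0:
        return None
    return math.log(s_prime / (1.0 - s_prime))


def p_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Uncorrected p-distances (mismatch proportions) between sequences.

    Symmetric with zero diagonal; entries in [0, 1].
    """
    mat = _as_matrix(seqs)
    n, length = mat.shape
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (mat[i + 1 :] != mat[i]).sum(axis=1) / length
    return d + d.T


@dataclass
class PopGenSummary:
    """Polymorphism measures and phylogeographic parameters for one dataset."""

    n_sequences: int
    length: int
    s: int
    a_n: int
    g_n: Optional[int]
    h_o: Optional[float]
    theta_w_locus: float
    theta_w_site: float
    pi_locus: float
    pi_site: float
    tajima_d: Optional[float]
    fu_fs: Optional[float]


def summarize_polymorphism(
    seqs: Sequence[str],
    pairing: Optional[Sequence[tuple[int, int]]] = None,
) -> PopGenSummary:
    """All eight statistics for an aligned sample of allele sequences.

    ``pairing`` gives, per diploid individual, the indices of its two allele
    copies in ``seqs``; it is required for the genotype-level measures G_N
    (distinct unordered allele pairs) and H_O (heterozygote proportion),
    which are reported as ``None`` when no pairing is supplied.
    """
    length = _check_alignment(seqs)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    s = count_segregating_sites(seqs)
    a_n = count_distinct_alleles(seqs)
    g_n = h_o = None
    if pairing is not None:
        genotypes = set()
        n_het = 0
        for ia, ib in pairing:
            genotypes.add(frozenset((seqs[ia], seqs[ib])))
            n_het += seqs[ia] != seqs[ib]
        g_n = len(genotypes)
        h_o = n_het / len(pairing)
    theta_locus, theta_site = watterson_theta(s, n, length)
    pi_locus, pi_site = nucleotide_diversity(seqs)
    return PopGenSummary(
        n_sequences=n,
        length=length,
        s=s,
        a_n=a_n,
        g_n=g_n,
        h_o=h_o,
        theta_w_locus=theta_locus,
        theta_w_site=theta_site,
        pi_locus=pi_locus,
        pi_site=pi_site,
        tajima_d=tajimas_d(seqs),
        fu_fs=fus_fs(seqs),
    )
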