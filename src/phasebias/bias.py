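"""Bias in phylogeographic statistics caused by omitting unresolved genotypes.

Pruning removes each unresolved individual and both of its allele copies; the
four statistics are then recomputed on the reduced sample and compared with
the phase-known values.  Delta signs follow the reporting convention in which
positive values always mean bias in the expected direction: diversity
(Watterson's theta, pi) decreases, so deltas are original minus pruned;
Tajima's D and Fu's F_S increase, so deltas are pruned minus original.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from phasebias.popgen import PopGenSummary, summarize_polymorphism
from phasebias.simulate import (
    AlleleAlignment,
    AmbiguousGenotype,
    DiploidIndividual,
    TruthDataset,
)

__all__ = [
    "BiasRecord",
    "RegressionFit",
    "PairedTestResult",
    "prune_unresolved",
    "compute_bias_table",
    "paired_one_tailed_t",
    "simple_regression",
]


def prune_unresolved(
    dataset: TruthDataset, unresolved_ids: Iterable[str]
) -> TruthDataset:
    """Remove unresolved individuals (and both their allele copies).

    Alignment columns are retained even if monomorphic afterwards; statistics
    on the pruned dataset therefore use the same locus length.
    """
    drop = set(unresolved_ids)
    known_ids = {ind.individual_id for ind in dataset.individuals}
    if not drop <= known_ids:
        raise ValueError("unresolved ids not a subset of the dataset's individuals")
    keep_inds = [i for i in dataset.individuals if i.individual_id not in drop]
    if 2 * len(keep_inds) < 2:
        raise ValueError("pruning would leave fewer than two sequences")
    keep_allele_ids = {a for i in keep_inds for a in (i.allele_a, i.allele_b)}
    ids, seqs = [], []
    for aid, seq in zip(dataset.alignment.ids, dataset.alignment.sequences):
        if aid in keep_allele_ids:
            ids.append(aid)
            seqs.append(seq)
    alignment = AlleleAlignment(ids=ids, sequences=seqs)
    genotypes = [
        g for g in dataset.genotypes if g.individual_id not in drop
    ]
    pos = {aid: i for i, aid in enumerate(ids)}
    pairing = [(pos[i.allele_a], pos[i.allele_b]) for i in keep_inds]
    summary = summarize_polymorphism(seqs, pairing)
    return TruthDataset(
        alignment=alignment,
        individuals=keep_inds,
        genotypes=genotypes,
        summary=summary,
        seed=dataset.seed,
        scaling=dataset.scaling,
        label=dataset.label,
    )


def _delta(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return a - b


@dataclass
class BiasRecord:
    """Signed parameter shifts for one dataset at one threshold.

    Positive values mean bias in the expected direction (diversity loss,
    D / F_S inflation); ``None`` marks a statistic undefined on either side.
    """

    label: str
    threshold: float
    n_omitted: int
    d_theta_w_site: Optional[float]   # original - pruned
    d_pi_site: Optional[float]        # original - pruned
    d_tajima_d: Optional[float]       # pruned - original
    d_fu_fs: Optional[float]          # pruned - original
    rel_theta_reduction: Optional[float]


def compute_bias_table(
    entries: Sequence[tuple[str, float, int, PopGenSummary, PopGenSummary]],
) -> list[BiasRecord]:
    """Bias records from (label, threshold, n_omitted, original, pruned) rows."""
    records = []
    for label, threshold, n_omitted, orig, pruned in entries:
        d_theta = _delta(orig.theta_w_site, pruned.theta_w_site)
        records.append(
            BiasRecord(
                label=label,
                threshold=threshold,
                n_omitted=n_omitted,
                d_theta_w_site=d_theta,
                d_pi_site=_delta(orig.pi_site, pruned.pi_site),
                d_tajima_d=_delta(pruned.tajima_d, orig.tajima_d),
                d_fu_fs=_delta(pruned.fu_fs, orig.fu_fs),
                rel_theta_reduction=(
                    d_theta / orig.theta_w_site
                    if d_theta is not None and orig.theta_w_site > 0
                    else None
                ),
            )
        )
    return records


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_one_tailed: float
    degenerate: bool = False


def paired_one_tailed_t(
    before: Sequence[float],
    after: Sequence[float],
    direction: str,
) -> PairedTestResult:
    """Paired t-test with a pre-specified one-tailed alternative.

    ``direction='greater'`` tests whether ``after`` exceeds ``before`` on
    average; ``'less'`` the reverse.  Zero variance of the differences gives a
    degenerate result (t = 0, P = 0.5) flagged as such.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    diffs = y - x
    if np.allclose(diffs.std(ddof=1), 0):
        return PairedTestResult(
            t=0.0, df=len(x) - 1, p_one_tailed=0.5, degenerate=True
        )
    res = stats.ttest_rel(y, x, alternative=direction)
    return PairedTestResult(
        t=float(res.statistic), df=len(x) - 1, p_one_tailed=float(res.pvalue)
    )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x with the F test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.allclose(x.var(), 0):
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = float(res.rvalue**2)
    df = (1, n - 2)
    f = r2 / (1 - r2) * (n - 2) if r2 < 1 else float("inf")
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_statistic=f,
        df=df,
        p_value=float(res.pvalue),
    )
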