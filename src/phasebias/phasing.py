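"""Bayesian gametic-phase reconstruction with per-individual confidence probabilities.

The sampler resolves the phase of multi-site heterozygotes ("ambiguous
genotypes") by Gibbs sampling over haplotype-pair decompositions.  For
individual i, a pair (x, complement) is drawn with probability proportional to

    pi_hat(x | H_-i) * pi_hat(complement | H_-i + {x})

where H_-i is the multiset of all other individuals' current haplotypes and
pi_hat is an approximate coalescent conditional in the Stephens--Donnelly
style: a new haplotype is most likely a copy of an existing one, with a
geometrically decaying penalty per mutational step away from it,

    pi_hat(x | H) propto sum_y n_y * rho^{d(x, y)}  for d(x, y) <= D,  + eps

with d the number of differing variable sites (parent-independent states, so
multiallelic sites cost one step per mismatch like any other), rho =
theta / (theta + n) the per-step weight, D the truncation radius of the
mutation kernel, and eps = rho^{D+1} a floor that keeps the chain ergodic when
a haplotype has no neighbour within D steps.  theta defaults to the Watterson
estimate from the genotype data.

Homozygotes and single-site heterozygotes are phase-trivial and fixed with
probability 1; their haplotypes still inform the conditional.  Confidence
probabilities are posterior pair frequencies over the retained post-burn-in
Gibbs samples.

Mixing aids (all preserving the stationary distribution of the main run):

* Individuals heterozygous at up to ``block_cap + 1`` sites are updated by
  exact enumeration of all 2^(h-1) decompositions; beyond that, a random
  block of ``block_cap`` phase bits is re-drawn jointly from its exact
  conditional while the remaining bits stay fixed.  Block moves cross fitness
  valleys that one-bit-at-a-time flips cannot.
* Chains start from a greedy scaffold: phase-trivial haplotypes seed the
  pool, then ambiguous individuals are phased one by one (fewest heterozygous
  sites first) at their conditional mode, instead of from random phase.
* Burn-in is annealed from ``anneal_start`` down to 1 (sampling scores raised
  to 1/T), which lets early iterations escape the self-reinforcing modes that
  arise when several individuals share an identical multi-site genotype.
  The main iterations always run at T = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from phasebias.popgen import harmonic_number
from phasebias.simulate import (
    AmbiguousGenotype,
    PAIR_FROM_CODE,
    BASES,
)

__all__ = [
    "PhasingRunConfig",
    "PairPosterior",
    "PhasingResult",
    "ThresholdedResult",
    "genotype_from_consensus",
    "enumerate_pair_candidates",
    "gibbs_phase",
    "select_best_replicate",
    "apply_confidence_threshold",
    "phase_dataset",
]

_VALID_CODES = set(BASES) | set(PAIR_FROM_CODE)


@dataclass(frozen=True)
class PhasingRunConfig:
    """Sampler protocol settings.

    Defaults follow the three-replicate protocol: 500 burn-in iterations, 500
    main iterations, thinning interval 1, and confidence thresholds 0.90 (the
    customary default) and 0.60.
    """

    burn_in: int = 500
    main_iters: int = 500
    thin: int = 1
    n_replicates: int = 3
    thresholds: tuple[float, ...] = (0.90, 0.60)
    theta_mode: str | float = "watterson"
    kernel_steps: int = 2
    block_cap: int = 10
    enumeration_cap: int = 20
    anneal_start: float = 3.0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.main_iters < 1 or self.thin < 1:
            raise ValueError("iteration counts must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.anneal_start < 1.0:
            raise ValueError("anneal_start must be >= 1 (1 disables annealing)")
        if self.block_cap < 1:
            raise ValueError("block_cap must be positive")
        for t in self.thresholds:
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")
        if isinstance(self.theta_mode, str) and self.theta_mode != "watterson":
            raise ValueError("theta_mode must be 'watterson' or a numeric value")


@dataclass
class PairPosterior:
    """Posterior over candidate haplotype pairs for one individual.

    ``candidates`` maps each unordered pair (as a sorted sequence tuple) to
    its posterior probability; probabilities sum to 1.  ``best_prob`` is the
    confidence probability of the best pair.
    """

    individual_id: str
    candidates: dict[tuple[str, str], float]
    best_pair: tuple[str, str]
    best_prob: float

    def top_pairs(self) -> list[tuple[str, str]]:
        """All candidate pairs tied (within 1e-12) for the highest probability."""
        return [
            p
            for p, v in self.candidates.items()
            if abs(v - self.best_prob) <= 1e-12
        ]


@dataclass
class PhasingResult:
    """One sampler replicate: per-individual posteriors plus run metadata.

    ``goodness`` is the replicate's average goodness-of-fit, defined
    operationally as the mean best-pair posterior probability over multi-site
    heterozygotes (1.0 when the dataset has none).
    """

    posteriors: dict[str, PairPosterior]
    seed: int
    goodness: float
    ambiguous_ids: tuple[str, ...]
    selected: bool = False


@dataclass
class ThresholdedResult:
    """Partition of the multi-site heterozygotes at one confidence threshold.

    An individual is resolved when its best-pair probability is >= the
    threshold (the boundary counts as resolved); the rest are unresolved.
    """

    threshold: float
    resolved: dict[str, PairPosterior]
    unresolved: dict[str, PairPosterior]

    @property
    def unresolved_ids(self) -> tuple[str, ...]:
        return tuple(self.unresolved)


def genotype_from_consensus(individual_id: str, consensus: str) -> AmbiguousGenotype:
    """Build an :class:`AmbiguousGenotype` from an ambiguity-coded consensus.

    Raises a parse error naming the offending position for characters outside
    {A,C,G,T} and the two-base ambiguity alphabet.
    """
    het = []
    for i, ch in enumerate(consensus):
        if ch not in _VALID_CODES:
            raise ValueError(
                f"invalid ambiguity code {ch!r} at position {i + 1} "
                f"of individual {individual_id}"
            )
        if ch in PAIR_FROM_CODE:
            het.append(i)
    return AmbiguousGenotype(individual_id, consensus, tuple(het))


def _site_base_pair(code: str) -> tuple[str, str]:
    """The unordered base pair carried at one site of a consensus sequence."""
    if code in PAIR_FROM_CODE:
        a, b = sorted(PAIR_FROM_CODE[code])
        return a, b
    return code, code


def enumerate_pair_candidates(
    genotype: AmbiguousGenotype, cap: int = 20
) -> list[tuple[str, str]]:
    """All distinct unordered haplotype-pair decompositions of a genotype.

    A genotype heterozygous at h sites has 2^(h-1) decompositions (1 when
    h <= 1).  Every returned pair collapses back to the genotype.  Refuses
    exhaustive enumeration above ``cap`` heterozygous sites.
    """
    het = genotype.het_positions
    h = len(het)
    if h > cap:
        raise ValueError(
            f"{h} heterozygous sites exceed the enumeration cap ({cap})"
        )
    base = list(genotype.consensus)
    if h == 0:
        seq = "".join(base)
        return [(seq, seq)]
    pairs = []
    site_pairs = [_site_base_pair(genotype.consensus[p]) for p in het]
    for mask in range(2 ** (h - 1)):
        a, b = base[:], base[:]
        for j, pos in enumerate(het):
            bit = (mask >> (j - 1)) & 1 if j > 0 else 0
            a[pos] = site_pairs[j][bit]
            b[pos] = site_pairs[j][1 - bit]
        pairs.append(tuple(sorted(("".join(a), "".join(b)))))
    return pairs


@njit(cache=True)
def _update_one(
    i,
    temp,
    greedy,
    hapmat,
    pair0,
    pair1,
    het_off,
    het_flat,
    bits,
    active,
    wtable,
    rho,
    eps,
    D,
    block_cap,
):
    """One Gibbs (or greedy) update of individual ``i``'s phase bits.

    Re-draws a block of phase bits jointly from its exact conditional: all
    bits but the pinned first one when 2^(h-1) enumeration fits under
    ``block_cap`` free bits, otherwise a uniformly chosen random block of
    ``block_cap`` bits with the rest held fixed.  The conditional of a
    candidate pair (x, complement) is

        (pi_x + eps) * (pi_c + cross + eps)

    with pi the truncated-kernel mass against every other active
    individual's current haplotypes, cross = rho^h the complement's kernel
    term for copying x itself, and sampling scores raised to 1/temp.
    """
    n = hapmat.shape[0]
    ncols = hapmat.shape[2]
    base = het_off[i]
    h = het_off[i + 1] - base

    # Choose the block of free phase-bit positions (bit 0 stays pinned so
    # each unordered pair is represented once).
    if h - 1 <= block_cap:
        k = h - 1
        subpos = np.empty(k, np.int64)
        for t in range(k):
            subpos[t] = t + 1
    else:
        k = block_cap
        idx = np.empty(h - 1, np.int64)
        for t in range(h - 1):
            idx[t] = t + 1
        for t in range(k):  # partial Fisher-Yates draw without replacement
            r = t + int(np.random.random() * (h - 1 - t))
            tmp = idx[t]
            idx[t] = idx[r]
            idx[r] = tmp
        subpos = idx[:k]
    c = 1 << k

    insub = np.zeros(ncols, np.uint8)
    for t in range(k):
        insub[het_flat[base + subpos[t]]] = 1

    # Rest distances: current haplotypes vs every other active individual's
    # haplotypes, over the columns outside the block (candidates only change
    # block columns, so this part is shared by all candidates).
    maxp = 2 * n
    d_a = np.empty(maxp, np.int64)
    d_b = np.empty(maxp, np.int64)
    hap_j = np.empty(maxp, np.int64)
    hap_r = np.empty(maxp, np.int64)
    npool = 0
    for j in range(n):
        if j == i or active[j] == 0:
            continue
        for r in range(2):
            da = 0
            db = 0
            for col in range(ncols):
                if insub[col] == 1:
                    continue
                v = hapmat[j, r, col]
                if v != hapmat[i, 0, col]:
                    da += 1
                if v != hapmat[i, 1, col]:
                    db += 1
            d_a[npool] = da
            d_b[npool] = db
            hap_j[npool] = j
            hap_r[npool] = r
            npool += 1

    # The kernel truncates at D steps and candidates only add distance, so a
    # pool haplotype at rest distance d contributes only to candidates that
    # flip at most D - d block sites away from its preferred bits.  Scatter
    # those exact contributions instead of scoring every candidate against
    # every haplotype.
    pi_x = np.zeros(c)
    pi_c = np.zeros(c)
    free = np.empty(k, np.int64)
    eq = np.empty(k, np.int64)
    comb = np.empty(k, np.int64)
    for side in range(2):
        dd = d_a if side == 0 else d_b
        pi = pi_x if side == 0 else pi_c
        for p in range(npool):
            if dd[p] > D:
                continue
            jj = hap_j[p]
            rr = hap_r[p]
            # Per block site: the preferred bit matches this haplotype (cost
            # of flipping = 1); when the haplotype matches neither base, the
            # bit is cost-free but the mismatch is unavoidable (eq site).
            # The x haplotype takes pair0 on bit 0 and pair1 on bit 1; the
            # complement takes the opposite, so the sides swap.
            baseline = dd[p]
            pref_mask = 0
            nf = 0
            ne = 0
            for t in range(k):
                col = het_flat[base + subpos[t]]
                v = hapmat[jj, rr, col]
                m0 = 1 if v != pair0[i, col] else 0
                m1 = 1 if v != pair1[i, col] else 0
                if side == 1:
                    m0, m1 = m1, m0
                if m0 == m1:
                    baseline += m0
                    eq[ne] = t
                    ne += 1
                else:
                    if m1 < m0:
                        pref_mask |= 1 << t
                        baseline += m1
                    else:
                        baseline += m0
                    free[nf] = t
                    nf += 1
            budget = D - baseline
            if budget < 0:
                continue
            # eq-site bits all carry the same cost, so the contribution
            # repeats over every assignment of those bits (ne <= budget'
            # is bounded because each eq site already added 1 to baseline).
            for esub in range(1 << ne):
                emask = 0
                for t in range(ne):
                    if (esub >> t) & 1 == 1:
                        emask |= 1 << eq[t]
                base_mask = pref_mask | emask
                pi[base_mask] += wtable[baseline]
                # flip f of the nf free sites, f <= budget
                for f in range(1, budget + 1):
                    if f > nf:
                        break
                    wf = wtable[baseline + f]
                    for t in range(f):
                        comb[t] = t
                    while True:
                        m = base_mask
                        for t in range(f):
                            m ^= 1 << free[comb[t]]
                        pi[m] += wf
                        t = f - 1
                        while t >= 0 and comb[t] == nf - f + t:
                            t -= 1
                        if t < 0:
                            break
                        comb[t] += 1
                        for u in range(t + 1, f):
                            comb[u] = comb[u - 1] + 1

    cross = rho**h if h <= D else 0.0
    scores = np.empty(c)
    total = 0.0
    inv_t = 1.0 / temp
    for cd in range(c):
        v = (pi_x[cd] + eps) * (pi_c[cd] + cross + eps)
        if temp != 1.0:
            v = v**inv_t
        scores[cd] = v
        total += v

    if greedy:
        choice = 0
        best = scores[0]
        for cd in range(1, c):
            if scores[cd] > best:
                best = scores[cd]
                choice = cd
    else:
        r = np.random.random() * total
        choice = c - 1
        acc = 0.0
        for cd in range(c):
            acc += scores[cd]
            if r <= acc:
                choice = cd
                break

    for t in range(k):
        bits[base + subpos[t]] = (choice >> t) & 1
    for j in range(h):
        col = het_flat[base + j]
        if bits[base + j] == 0:
            hapmat[i, 0, col] = pair0[i, col]
            hapmat[i, 1, col] = pair1[i, col]
        else:
            hapmat[i, 0, col] = pair1[i, col]
            hapmat[i, 1, col] = pair0[i, col]


@njit(cache=True)
def _run_chain(
    hapmat,
    pair0,
    pair1,
    het_off,
    het_flat,
    amb,
    init_order,
    bits,
    active,
    wtable,
    rho,
    eps,
    D,
    block_cap,
    burn_in,
    main_iters,
    thin,
    anneal_start,
    seed,
    keys_out,
):
    """One replicate: greedy scaffold, annealed burn-in, tallied main run.

    Returns the number of retained samples; ``keys_out[s, t]`` holds the
    phase bits of the t-th ambiguous individual at retained sample s, packed
    into a bitmask (bit j = phase bit of its j-th heterozygous site).
    """
    np.random.seed(seed)
    n_amb = amb.shape[0]

    # Greedy scaffold: phase-trivial haplotypes are active from the start;
    # ambiguous individuals enter at their conditional mode, fewest
    # heterozygous sites first.
    for t in range(n_amb):
        i = init_order[t]
        _update_one(
            i, 1.0, True, hapmat, pair0, pair1, het_off, het_flat,
            bits, active, wtable, rho, eps, D, block_cap,
        )
        active[i] = 1

    for s in range(burn_in):
        temp = anneal_start + (1.0 - anneal_start) * (s + 1) / burn_in
        for t in range(n_amb):
            _update_one(
                amb[t], temp, False, hapmat, pair0, pair1, het_off, het_flat,
                bits, active, wtable, rho, eps, D, block_cap,
            )

    ret = 0
    for s in range(main_iters):
        for t in range(n_amb):
            _update_one(
                amb[t], 1.0, False, hapmat, pair0, pair1, het_off, het_flat,
                bits, active, wtable, rho, eps, D, block_cap,
            )
        if s % thin == 0:
            for t in range(n_amb):
                i = amb[t]
                h = het_off[i + 1] - het_off[i]
                key = 0
                for j in range(h):
                    if bits[het_off[i] + j] == 1:
                        key |= 1 << j
                keys_out[ret, t] = key
            ret += 1
    return ret


class _Problem:
    """Array form of a genotype set over its variable columns."""

    def __init__(self, genotypes: Sequence[AmbiguousGenotype], config: PhasingRunConfig):
        self.config = config
        self.genotypes = list(genotypes)
        if not self.genotypes:
            raise ValueError("no individuals to phase")
        length = len(self.genotypes[0].consensus)
        for g in self.genotypes:
            if len(g.consensus) != length:
                raise ValueError("genotype consensus sequences differ in length")
            genotype_from_consensus(g.individual_id, g.consensus)  # validates

        # Variable columns: heterozygous anywhere, or homozygous states differ.
        var_cols: list[int] = []
        for col in range(length):
            states = {g.consensus[col] for g in self.genotypes}
            if len(states) > 1 or any(s in PAIR_FROM_CODE for s in states):
                var_cols.append(col)
        self.var_cols = var_cols
        ncols = len(var_cols)
        n = len(self.genotypes)
        n_haps = 2 * n

        if isinstance(config.theta_mode, str):
            theta = ncols / harmonic_number(max(n_haps - 1, 1)) if ncols else 1.0
        else:
            theta = float(config.theta_mode)
        self.rho = theta / (theta + n_haps)
        self.D = config.kernel_steps
        self.eps = self.rho ** (self.D + 1)
        # Kernel-weight lookup: rho^d within the truncation radius, else 0.
        steps = np.arange(ncols + 2)
        self.wtable = np.where(
            steps <= self.D, self.rho ** steps.astype(float), 0.0
        )

        # pair0/pair1: the two base choices per individual and column (equal
        # at columns where the individual is homozygous).
        self.pair0 = np.empty((n, ncols), dtype=np.uint8)
        self.pair1 = np.empty((n, ncols), dtype=np.uint8)
        het_flat: list[int] = []
        het_off = [0]
        for i, g in enumerate(self.genotypes):
            for k, col in enumerate(var_cols):
                a, b = _site_base_pair(g.consensus[col])
                self.pair0[i, k] = ord(a)
                self.pair1[i, k] = ord(b)
                if a != b:
                    het_flat.append(k)
            het_off.append(len(het_flat))
        self.het_off = np.array(het_off, dtype=np.int64)
        self.het_flat = np.array(het_flat, dtype=np.int64)

        het_counts = np.diff(self.het_off)
        if het_counts.size and het_counts.max() > 63:
            raise ValueError(
                "more than 63 heterozygous sites in one individual"
            )
        self.ambiguous = [i for i in range(n) if het_counts[i] >= 2]
        self._ambiguous_set = set(self.ambiguous)
        self.amb = np.array(self.ambiguous, dtype=np.int64)
        self.init_order = np.array(
            sorted(self.ambiguous, key=lambda i: (het_counts[i], i)),
            dtype=np.int64,
        )

    def initial_state(self):
        """Fresh per-chain state: all phase bits 0, trivial individuals active."""
        n = len(self.genotypes)
        ncols = self.pair0.shape[1]
        bits = np.zeros(len(self.het_flat), dtype=np.uint8)
        hapmat = np.empty((n, 2, ncols), dtype=np.uint8)
        hapmat[:, 0, :] = self.pair0
        hapmat[:, 1, :] = self.pair1
        active = np.ones(n, dtype=np.uint8)
        active[self.amb] = 0
        return hapmat, bits, active

    def pair_sequences(self, i: int, bits: Sequence[int]) -> tuple[str, str]:
        g = self.genotypes[i]
        a, b = list(g.consensus), list(g.consensus)
        hets = self.het_flat[self.het_off[i] : self.het_off[i + 1]]
        for j, k in enumerate(hets):
            col = self.var_cols[k]
            pa, pb = _site_base_pair(g.consensus[col])
            pair = (pa, pb)
            a[col] = pair[bits[j]]
            b[col] = pair[1 - bits[j]]
        return tuple(sorted(("".join(a), "".join(b))))


def _decode_key(key: int, h: int) -> tuple[int, ...]:
    return tuple((key >> j) & 1 for j in range(h))


def gibbs_phase(
    genotypes: Sequence[AmbiguousGenotype],
    config: PhasingRunConfig,
    seed: int,
) -> PhasingResult:
    """Run one Gibbs-sampler replicate and return per-individual posteriors."""
    problem = _Problem(genotypes, config)

    n_retained = (config.main_iters - 1) // config.thin + 1
    tally: dict[int, dict[int, int]] = {}
    if problem.ambiguous:
        hapmat, bits, active = problem.initial_state()
        keys_out = np.zeros((n_retained, len(problem.amb)), dtype=np.int64)
        ret = _run_chain(
            hapmat,
            problem.pair0,
            problem.pair1,
            problem.het_off,
            problem.het_flat,
            problem.amb,
            problem.init_order,
            bits,
            active,
            problem.wtable,
            problem.rho,
            problem.eps,
            problem.D,
            config.block_cap,
            config.burn_in,
            config.main_iters,
            config.thin,
            config.anneal_start,
            seed,
            keys_out,
        )
        if ret == 0:
            raise RuntimeError("no retained Gibbs samples")
        for t, i in enumerate(problem.ambiguous):
            col = keys_out[:ret, t]
            keys, counts = np.unique(col, return_counts=True)
            tally[i] = {int(k): int(c) for k, c in zip(keys, counts)}

    posteriors: dict[str, PairPosterior] = {}
    goodness_terms = []
    for i, g in enumerate(problem.genotypes):
        h = int(problem.het_off[i + 1] - problem.het_off[i])
        if i in tally:
            total = sum(tally[i].values())
            cands = {
                problem.pair_sequences(i, _decode_key(key, h)): cnt / total
                for key, cnt in sorted(tally[i].items())
            }
        else:
            pair = problem.pair_sequences(i, (0,) * h)
            cands = {pair: 1.0}
        best_pair = max(cands, key=lambda p: (cands[p], p))
        best_prob = cands[best_pair]
        posteriors[g.individual_id] = PairPosterior(
            g.individual_id, cands, best_pair, best_prob
        )
        if i in problem._ambiguous_set:
            goodness_terms.append(best_prob)
    goodness = float(np.mean(goodness_terms)) if goodness_terms else 1.0
    return PhasingResult(
        posteriors=posteriors,
        seed=seed,
        goodness=goodness,
        ambiguous_ids=tuple(
            problem.genotypes[i].individual_id for i in problem.ambiguous
        ),
    )


def select_best_replicate(
    replicates: Sequence[PhasingResult], seed: int = 0
) -> PhasingResult:
    """Pick the replicate with the best average goodness-of-fit.

    Ties among replicates break towards the lowest run seed.  Within the
    selected replicate, per-individual ties among equally probable best pairs
    are broken by a seeded random choice, so the selection is reproducible.
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    best = max(replicates, key=lambda r: (r.goodness, -r.seed))
    rng = np.random.default_rng(seed)
    for ind_id in sorted(best.posteriors):
        post = best.posteriors[ind_id]
        top = post.top_pairs()
        if len(top) > 1:
            post.best_pair = top[int(rng.integers(len(top)))]
    best.selected = True
    return best


def apply_confidence_threshold(
    result: PhasingResult, threshold: float
) -> ThresholdedResult:
    """Partition multi-site heterozygotes into resolved / unresolved.

    Best-pair probability >= threshold counts as resolved ("below-threshold"
    genotypes are the unresolved ones).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    resolved, unresolved = {}, {}
    for ind_id in result.ambiguous_ids:
        post = result.posteriors[ind_id]
        (resolved if post.best_prob >= threshold else unresolved)[ind_id] = post
    return ThresholdedResult(threshold, resolved, unresolved)


def phase_dataset(
    genotypes: Sequence[AmbiguousGenotype],
    config: PhasingRunConfig,
    seed: int,
) -> tuple[PhasingResult, list[PhasingResult]]:
    """Replicate-run protocol: n_replicates independent chains, best selected."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1)) + 1
        for s in ss.spawn(config.n_replicates + 1)
    ]
    replicates = [
        gibbs_phase(genotypes, config, rep_seeds[k])
        for k in range(config.n_replicates)
    ]
    best = select_best_replicate(replicates, seed=rep_seeds[-1])
    return best, replicates
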