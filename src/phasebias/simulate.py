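"""Phase-known diploid dataset simulation under a neutral coalescent with HKY85 mutation.

The generator emulates a single panmictic population of constant haploid
effective size: a Kingman coalescent gene tree for 2N allele copies is drawn
with msprime, sequences are evolved down the tree under an HKY85 substitution
model (transition probabilities from the matrix exponential of the scaled
rate matrix), allele copies are paired uniformly at random into diploid
individuals, and each individual's two alleles are collapsed into a consensus
sequence carrying IUPAC ambiguity codes at heterozygous positions.  Suites of
datasets conditioned on exact segregating-site counts are produced by
rejection sampling over (tree, mutation-rate) draws, one tree per dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import msprime
import numpy as np
from scipy.linalg import expm

from phasebias.popgen import (
    count_segregating_sites,
    harmonic_number,
    summarize_polymorphism,
    PopGenSummary,
)

__all__ = [
    "SimulationConfig",
    "GeneTree",
    "AlleleAlignment",
    "DiploidIndividual",
    "AmbiguousGenotype",
    "TruthDataset",
    "hky_rate_matrix",
    "kappa_from_tstv",
    "simulate_gene_tree",
    "evolve_alignment",
    "assemble_genotypes",
    "generate_suite",
    "IUPAC_PAIR_CODES",
    "BASES",
]

BASES = "ACGT"

# Two-base IUPAC ambiguity codes, keyed by the unordered base pair.
IUPAC_PAIR_CODES = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
PAIR_FROM_CODE = {v: k for k, v in IUPAC_PAIR_CODES.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the simulated datasets.

    Defaults reproduce the study conditions: 50 diploid individuals (100
    allele copies), a 250-bp non-recombining locus, haploid N_e = 1000,
    population age 2N_e = 2000 generations (the coalescent is run to the MRCA
    unconstrained; with n = 100 and N_e = 1000 the expected TMRCA is ~1980
    generations, matching the nominal age), HKY85 with base frequencies
    A 0.30 / C 0.20 / G 0.15 / T 0.35 and ts/tv = 2.5, and segregating-site
    targets {5, 10, 15, 20, 25, 30, 35} with five replicate datasets each.

    ``scaling_range`` bounds the per-site per-generation substitution rate
    used in rejection sampling.  The default (1e-6, 1e-5) is wide enough to
    reach the lowest polymorphism targets; ``PRINTED_SCALING_RANGE`` preserves
    the narrower trial-and-error range quoted with the original design.
    """

    n_individuals: int = 50
    locus_length: int = 250
    ne_haploid: float = 1000.0
    age_generations: float = 2000.0
    hky_freqs: tuple[float, float, float, float] = (0.30, 0.20, 0.15, 0.35)
    tstv_ratio: float = 2.5
    scaling_range: tuple[float, float] = (1.0e-6, 1.0e-5)
    s_targets: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35)
    replicates_per_target: int = 5
    seed: int = 1
    max_attempts: int = 20000

    PRINTED_SCALING_RANGE = (9.0e-6, 1.0e-5)

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.locus_length < 1:
            raise ValueError("counts must be positive")
        if self.ne_haploid <= 0:
            raise ValueError("effective population size must be positive")
        if abs(sum(self.hky_freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if any(f <= 0 for f in self.hky_freqs):
            raise ValueError("base frequencies must be positive")
        if self.tstv_ratio <= 0:
            raise ValueError("ts/tv ratio must be positive")
        lo, hi = self.scaling_range
        if not (0 < lo <= hi):
            raise ValueError("invalid scaling range")
        if self.replicates_per_target < 0:
            raise ValueError("replicates_per_target must be non-negative")


@dataclass
class GeneTree:
    """Rooted binary coalescent tree with branch lengths in generations.

    ``parent[v]`` is the parent node of v (-1 at the root), ``time[v]`` the
    node age in generations; tips are nodes 0 .. n_tips-1 with time 0.
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.time[: self.n_tips]) <= tol))


@dataclass
class AlleleAlignment:
    """Ordered haploid sequences over {A,C,G,T} with allele identifiers."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("ragged alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class DiploidIndividual:
    """A diploid individual: an unordered pair of allele-copy identifiers."""

    individual_id: str
    allele_a: str
    allele_b: str


@dataclass
class AmbiguousGenotype:
    """Phase-unknown consensus of one individual's two alleles.

    ``consensus`` carries a two-base IUPAC ambiguity code at every position
    where the alleles differ; ``het_positions`` lists those positions
    (0-based).  Individuals heterozygous at >= 2 positions are "ambiguous":
    their phase cannot be read off the consensus.
    """

    individual_id: str
    consensus: str
    het_positions: tuple[int, ...]

    @property
    def n_het_sites(self) -> int:
        return len(self.het_positions)

    @property
    def is_ambiguous(self) -> bool:
        return self.n_het_sites >= 2


@dataclass
class TruthDataset:
    """Phase-known alignment, diploid pairing, consensus genotypes and summary."""

    alignment: AlleleAlignment
    individuals: list[DiploidIndividual]
    genotypes: list[AmbiguousGenotype]
    summary: PopGenSummary
    seed: int
    scaling: float
    label: str = ""

    @property
    def n_ambiguous(self) -> int:
        return sum(g.is_ambiguous for g in self.genotypes)

    def true_pair(self, individual_id: str) -> tuple[str, str]:
        """The individual's two true allele sequences (unordered)."""
        ind = next(i for i in self.individuals if i.individual_id == individual_id)
        lookup = dict(zip(self.alignment.ids, self.alignment.sequences))
        return tuple(sorted((lookup[ind.allele_a], lookup[ind.allele_b])))

    def pairing_indices(self) -> list[tuple[int, int]]:
        pos = {aid: i for i, aid in enumerate(self.alignment.ids)}
        return [(pos[i.allele_a], pos[i.allele_b]) for i in self.individuals]


def kappa_from_tstv(tstv_ratio: float, freqs: Sequence[float]) -> float:
    """HKY85 rate-ratio kappa giving the requested expected ts:tv count ratio.

    At stationarity the expected transition:transversion substitution-count
    ratio is R = kappa (pi_A pi_G + pi_C pi_T) / (pi_R pi_Y); the ts/tv ratio
    quoted with the study design is interpreted as this count ratio R.
    """
    a, c, g, t = freqs
    purines, pyrimidines = a + g, c + t
    return tstv_ratio * purines * pyrimidines / (a * g + c * t)


def hky_rate_matrix(
    freqs: Sequence[float], tstv_ratio: float
) -> np.ndarray:
    """HKY85 instantaneous rate matrix (states A,C,G,T), normalized so the
    expected substitution rate at stationarity is 1 per site per unit time."""
    kappa = kappa_from_tstv(tstv_ratio, freqs)
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


def simulate_gene_tree(config: SimulationConfig, seed: int) -> GeneTree:
    """Draw one neutral Kingman coalescent tree for the configured sample.

    All 2N lineages coalesce in a single panmictic population of the
    configured haploid size; branch lengths are in generations.
    """
    if config.n_alleles < 2:
        raise ValueError("need at least two allele copies")
    ts = msprime.sim_ancestry(
        samples=config.n_alleles,
        ploidy=1,
        population_size=config.ne_haploid,
        random_seed=max(1, int(seed) % (2**32 - 1)),
    )
    tree = ts.first()
    n_nodes = ts.num_nodes
    parent = np.array([tree.parent(v) for v in range(n_nodes)], dtype=np.int64)
    time = np.array([tree.time(v) for v in range(n_nodes)], dtype=float)
    return GeneTree(parent=parent, time=time, n_tips=config.n_alleles)


def evolve_alignment(
    tree: GeneTree,
    config: SimulationConfig,
    scaling: float,
    seed: int,
) -> AlleleAlignment:
    """Evolve L nucleotide characters down the tree under HKY85.

    The root sequence is drawn from the equilibrium base frequencies; each
    branch applies the transition matrix expm(Q * scaling * branch_length),
    so ``scaling`` is the expected number of substitutions per site per
    generation.
    """
    if scaling < 0:
        raise ValueError("scaling must be non-negative")
    rng = np.random.default_rng(seed)
    q = hky_rate_matrix(config.hky_freqs, config.tstv_ratio)
    length = config.locus_length
    pi = np.asarray(config.hky_freqs)

    order = np.argsort(tree.time)[::-1]  # root first, tips last
    states = np.empty((tree.n_nodes, length), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(4, size=length, p=pi)
    for v in order:
        if v == root:
            continue
        p = tree.parent[v]
        branch = tree.time[p] - tree.time[v]
        if scaling * branch == 0:
            states[v] = states[p]
            continue
        trans = expm(q * scaling * branch)
        cum = np.cumsum(trans, axis=1)
        r = rng.random(length)
        states[v] = (r[:, None] > cum[states[p]]).sum(axis=1)

    seqs = ["".join(BASES[b] for b in states[i]) for i in range(tree.n_tips)]
    ids = [f"allele{i:03d}" for i in range(tree.n_tips)]
    return AlleleAlignment(ids=ids, sequences=seqs)


def collapse_to_consensus(seq_a: str, seq_b: str) -> tuple[str, tuple[int, ...]]:
    """IUPAC consensus of two aligned allele sequences.

    At each differing position the code is the two-base ambiguity letter for
    the unordered base pair; the collapse is lossless up to phase.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("allele sequences differ in length")
    out = []
    het = []
    for i, (x, y) in enumerate(zip(seq_a, seq_b)):
        if x == y:
            out.append(x)
        else:
            out.append(IUPAC_PAIR_CODES[frozenset((x, y))])
            het.append(i)
    return "".join(out), tuple(het)


def assemble_genotypes(
    alignment: AlleleAlignment, seed: int
) -> tuple[list[DiploidIndividual], list[AmbiguousGenotype]]:
    """Pair allele copies into diploid individuals uniformly at random.

    The pairing is a perfect matching (each allele copy used exactly once),
    emulating random mating in a sexual out-crossing species.  Allele ids are
    rewritten in place to ``ind<i>_a`` / ``ind<i>_b``.
    """
    n = len(alignment)
    if n % 2:
        raise ValueError("odd number of allele copies cannot be paired")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    individuals: list[DiploidIndividual] = []
    genotypes: list[AmbiguousGenotype] = []
    new_ids = list(alignment.ids)
    for k in range(n // 2):
        ia, ib = int(perm[2 * k]), int(perm[2 * k + 1])
        ind_id = f"ind{k:03d}"
        new_ids[ia] = f"{ind_id}_a"
        new_ids[ib] = f"{ind_id}_b"
        individuals.append(
            DiploidIndividual(ind_id, allele_a=new_ids[ia], allele_b=new_ids[ib])
        )
        consensus, het = collapse_to_consensus(
            alignment.sequences[ia], alignment.sequences[ib]
        )
        genotypes.append(AmbiguousGenotype(ind_id, consensus, het))
    alignment.ids = new_ids
    return individuals, genotypes


def _propose_scaling(
    target_s: int, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Propose a substitution rate biased towards the target S.

    Centres proposals on the rate whose expected segregating-site count under
    Watterson's formula equals the target (E[S] = a1 * 2 N_e mu L for a
    haploid-size-N_e coalescent), with lognormal jitter, clipped to the
    configured range.  Proposal choice only affects rejection-sampling
    efficiency, not the conditional distribution of accepted datasets.
    """
    a1 = harmonic_number(config.n_alleles - 1)
    centre = target_s / (a1 * 2 * config.ne_haploid * config.locus_length)
    jitter = math.exp(rng.normal(0.0, 0.25))
    lo, hi = config.scaling_range
    return float(min(max(centre * jitter, lo), hi))


def _build_dataset(
    alignment: AlleleAlignment,
    pair_seed: int,
    sim_seed: int,
    scaling: float,
    label: str,
) -> TruthDataset:
    individuals, genotypes = assemble_genotypes(alignment, pair_seed)
    pos = {aid: i for i, aid in enumerate(alignment.ids)}
    pairing = [
        (pos[ind.allele_a], pos[ind.allele_b]) for ind in individuals
    ]
    summary = summarize_polymorphism(alignment.sequences, pairing)
    return TruthDataset(
        alignment=alignment,
        individuals=individuals,
        genotypes=genotypes,
        summary=summary,
        seed=sim_seed,
        scaling=scaling,
        label=label,
    )


def simulate_dataset(
    config: SimulationConfig, scaling: float, seed: int, label: str = ""
) -> TruthDataset:
    """One unconditioned dataset: tree, alignment, random pairing, consensus."""
    ss = np.random.SeedSequence(seed)
    tree_seed, evo_seed, pair_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(3)
    )
    tree = simulate_gene_tree(config, tree_seed)
    alignment = evolve_alignment(tree, config, scaling, evo_seed)
    return _build_dataset(alignment, pair_seed, seed, scaling, label)


def generate_suite(config: SimulationConfig) -> list[TruthDataset]:
    """Generate the conditioned dataset suite.

    For every target segregating-site count, rejection-sample (tree, rate)
    draws until ``replicates_per_target`` datasets whose realized S equals the
    target are found; one coalescent tree per dataset.  Fully reproducible
    from ``config.seed``.
    """
    if not config.s_targets:
        raise ValueError("no segregating-site targets requested")
    root_ss = np.random.SeedSequence(config.seed)
    datasets: list[TruthDataset] = []
    counter = 0
    for target in config.s_targets:
        for rep in range(config.replicates_per_target):
            counter += 1
            label = f"Sim{counter:02d}"
            dataset = None
            attempt_ss = root_ss.spawn(1)[0]
            rng = np.random.default_rng(attempt_ss)
            for attempt in range(config.max_attempts):
                scaling = _propose_scaling(target, config, rng)
                seed = int(rng.integers(1, 2**31 - 1))
                ss = np.random.SeedSequence(seed)
                tree_seed, evo_seed = (
                    int(s.generate_state(1)[0] % (2**31 - 1)) + 1
                    for s in ss.spawn(2)
                )
                tree = simulate_gene_tree(config, tree_seed)
                alignment = evolve_alignment(tree, config, scaling, evo_seed)
                if count_segregating_sites(alignment.sequences) == target:
                    pair_seed = int(rng.integers(1, 2**31 - 1))
                    dataset = _build_dataset(
                        alignment, pair_seed, seed, scaling, label
                    )
                    break
            if dataset is None:
                raise RuntimeError(
                    f"could not realize S={target} within "
                    f"{config.max_attempts} attempts; widen scaling_range"
                )
            datasets.append(dataset)
    return datasets
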