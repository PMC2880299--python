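# Methods

This document records the models, parameter choices, and design decisions
behind each stage of the pipeline, including where the implementation makes a
documented substitution for an under-specified or tool-specific procedure.

## 1. Simulation of phase-known datasets

**Gene trees.** Each dataset's 100 allele copies descend from a single
neutral coalescent gene tree simulated with `msprime` under a haploid model
(`ploidy=1`) with effective size N<sub>e</sub> = 1000. The tree age is not
constrained; the expected time to coalescence of a pair is N<sub>e</sub>
generations. Ultrametricity and the pairwise-coalescence mean are covered by
tests.

**Sequence evolution.** Sequences of length 250 evolve along the tree under
HKY85 with stationary frequencies (A, C, G, T) = (0.30, 0.20, 0.15, 0.35) and
a transition/transversion ratio of 2.5. The ratio is interpreted as the ratio
of *expected counts* (R = κ(π<sub>A</sub>π<sub>G</sub> +
π<sub>C</sub>π<sub>T</sub>) / ((π<sub>A</sub>+π<sub>G</sub>)(π<sub>C</sub>+π<sub>T</sub>)))
rather than the raw rate multiplier κ, giving κ ≈ 5.38. The rate matrix is
normalized to one expected substitution per site per unit time; transition
probabilities along each branch use the matrix exponential. Root states are
drawn from the stationary distribution.

**Conditioning on S.** Datasets are accepted only when they hit an exact
target number of segregating sites, S ∈ {5, 10, 15, 20, 25, 30, 35}, five
replicates each. Each proposal draws a branch-length scaling (mutation rate
per site per generation) centred at the Watterson-implied value
S / (a₁ · 2N<sub>e</sub>L) with lognormal jitter (σ = 0.25), clamped to
[10⁻⁶, 10⁻⁵], then simulates and checks S. Rejection sampling conditions the
suite on the observed design without distorting tree shape.

**Diploids and genotypes.** The 100 alleles are paired at random into 50
diploid individuals. Each pair is collapsed to a consensus sequence with
IUPAC two-base ambiguity codes at heterozygous sites; individuals with ≥ 2
heterozygous sites are the "ambiguous genotypes" whose phase must be
reconstructed. All randomness flows from a single `SeedSequence`-derived
stream per dataset, so suites regenerate bit-identically from the seed.

## 2. Phasing engine

The built-in phaser is a Gibbs sampler over per-individual haplotype pairs
with a coalescent-flavored conditional prior: the probability of a candidate
haplotype x given the current set H of other haplotypes is approximated by
π̂(x | H) = Σ<sub>y∈H</sub> ρ^d(x,y), where d is the Hamming distance over
variable columns, ρ = θ/(θ + n) with θ the Watterson estimate from the
variable columns, and terms beyond a truncation depth D (default 2 mutational
steps) are dropped. A pair (x, x̄) is scored
(π̂(x) + ε)(π̂(x̄) + cross + ε) with ε = ρ^(D+1) a floor for unseen
haplotypes and `cross` = ρ^h accounting for the partner being one copy away
when the heterozygosity h is within D.

**Truncation as the speed lever.** Because contributions decay as ρ^d and
ρ ≪ 1 in this regime, candidates further than D steps from every existing
haplotype are indistinguishable up to ε. The sampler exploits this with an
exact budget-limited enumeration: for each neighbour haplotype it scatters
probability mass only to the candidate assignments within D mismatches,
enumerated combinatorially instead of scoring all 2^(h−1) decompositions
against the whole pool. This is exact with respect to the truncated kernel
(regression-checked against the dense implementation) and makes 500+500
iterations on 50 individuals run in seconds (`numba`-compiled kernels).

**Mixing aids.** Three standard MCMC devices address frozen chains observed
with plain single-site Gibbs updates (mutually reinforcing identical
genotypes): (i) block updates — per sweep, each individual resamples either
its full 2^(h−1) pair space (h−1 ≤ 10 heterozygous sites) or a random 10-site
block; (ii) a greedy scaffold initialization that phases unambiguous
individuals first and seeds ambiguous ones at their conditional mode, in
increasing heterozygosity order; (iii) a temperature anneal from T = 3 to
T = 1 across the burn-in. All three leave the stationary distribution at
T = 1 untouched; sampled posteriors are verified against an independent
exhaustive-enumeration oracle on small problems.

**Protocol.** Three replicate chains (independent sub-seeds) of 500 burn-in +
500 retained iterations, thinning 1. Replicate agreement is summarized by a
"goodness" score — the mean posterior probability of each ambiguous
individual's best pair — and the best-goodness replicate (ties to the lowest
seed) supplies the final calls. Per-individual confidence is the posterior
frequency of the best pair; thresholds 0.90 and 0.60 partition ambiguous
individuals into resolved and unresolved.

## 3. Evaluation

For each confidently resolved individual the inferred pair is compared with
the true pair (order-free). Errors are classified by the status of each
inferred haplotype — correct (one of the individual's true alleles),
miscalled-known (wrong, but present elsewhere in the true allele pool), or
novel (absent from the pool) — giving five classes: E_COR+NOV, E_COR+MIS,
E_MIS+MIS, E_MIS+NOV, E_NOV+NOV. Note a structural property used as a test
oracle: any candidate pair that collapses back to the observed genotype
agrees with the truth at every homozygous site, and if one haplotype is fully
correct the complementarity of heterozygous sites forces the other to be
correct too — so the mixed E_COR+\* classes cannot occur for
complement-consistent callers and flag bookkeeping bugs if seen.

Unresolved individuals are counted (N_LCP), along with how many of their best
pairs were nevertheless correct. Lost alleles (N_LOST) are true allele
sequences whose every carrier is unresolved. Divergence skew compares mean
pairwise p-distance from lost alleles to the remaining pool against the
dataset-wide mean. Genotypic configurations record, per ambiguous individual,
whether its two true alleles are rare (frequency < 0.05) or singletons.

## 4. Bias in summary statistics

Pruning removes each unresolved individual and both of its allele copies;
locus length is unchanged. Four statistics are computed before and after:
Watterson's Θ<sub>W</sub> (per site), nucleotide diversity π (per site),
Tajima's D, and Fu's F<sub>S</sub> (Ewens-distribution S′ with θ set to the
mean pairwise difference; the Stirling-number sum is evaluated exactly with
big integers and log-space normalization). Deltas follow the reporting
convention that positive means "bias in the expected direction": Θ<sub>W</sub>
and π as original − pruned, D and F<sub>S</sub> as pruned − original.
Dataset-level shifts are tested with paired one-tailed t-tests (direction
pre-specified; zero-variance differences return a flagged degenerate result
rather than an error) and related to the number of omissions by ordinary
least squares with the F test of the slope.

Statistics undefined on a dataset (e.g. D with S = 0, F<sub>S</sub> with a
single haplotype) are `None` and excluded from aggregation, not coerced to 0.

## 5. Parsimony networks and rooting

Distinct haplotypes are linked in increasing pairwise-distance order
(Kruskal-style, deterministic tie-breaks) up to the 95% connection limit: the
largest step count j whose probability of parsimony meets 0.95, evaluated
under a per-site Poisson model with the Jukes–Cantor load
λ = −¾ ln(1 − 4j/(3L)); a j-step pair is parsimonious with probability
(λe^(−λ) / (¾(1 − e^(−4λ/3))))^j. Multi-step links insert unobserved
intermediate nodes; haplotypes unreachable within the limit form separate
networks.

Root probabilities use a surrogate outgroup weight: relative sample frequency
× 1/(1 + mean graph distance to the other observed haplotypes), normalized
within each network and scaled by the network's share of sampled copies for
the dataset-level root. The downstream comparison is qualitative — the root
comparison flags a change when the pruned dataset's root sequence differs or
when the surviving companions of the original root's network component change
— so the weight formula is isolated in one function for substitution.

## 6. Numerical and reproducibility choices

- All stochastic entry points take integer seeds; internal streams derive via
  `numpy.random.SeedSequence.spawn`, so component seeds never collide and
  every result regenerates exactly.
- Exact integer arithmetic where distributions demand it (Stirling numbers);
  log-space evaluation elsewhere.
- Heterozygosity per individual is capped at 63 sites (pair states are
  tallied as 64-bit masks); the benchmark's maximum is far below this.
- User-facing coordinates are 1-based inclusive; internals are 0-based
  half-open.

## 7. Known limitations

- The phasing prior is a truncated product approximation, not the full
  recursive conditional likelihood of mature phasing software; it has no
  recombination model (appropriate for a 250 bp non-recombining locus) and
  treats sites as exchangeable. Absolute error rates are therefore specific
  to this engine; the bias analysis takes the resolved/unresolved partition
  as given, whatever the phaser.
- The generator covers one demographic scenario (constant-size neutral
  panmixia). Bias directions under growth, structure, or selection are out of
  scope.
- The parsimony-probability formula is a standard surrogate for the cited
  network method's internal recursion; connection limits can differ by one
  step from other implementations at boundary probabilities.
- The goodness score used to pick the best replicate is a self-consistency
  measure, not a likelihood; replicates rarely disagree at the benchmark's
  chain lengths.
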