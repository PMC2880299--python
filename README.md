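# phasebias

Quantify how errors and omissions in statistical haplotype-phase
reconstruction bias downstream phylogeographic inference.

Direct sequencing of a diploid PCR product yields, for each individual, a
single consensus sequence with IUPAC ambiguity codes at heterozygous
positions. Individuals heterozygous at two or more positions ("ambiguous
genotypes") cannot be phased by eye, so studies of nuclear loci routinely
reconstruct haplotype pairs with a Bayesian phasing algorithm and then either
accept every best-pair call or discard individuals whose call falls below a
confidence threshold. Both choices have consequences: confident errors
introduce false haplotypes, while discarding unresolved individuals
preferentially removes carriers of rare, divergent alleles — deflating
diversity estimators and inflating neutrality tests.

This package implements the full benchmark pipeline end to end:

1. **Simulation** — phase-known diploid datasets (50 individuals, 100 allele
   copies, 250 bp) on neutral coalescent gene trees (haploid N<sub>e</sub> =
   1000, via `msprime`) with HKY85 sequence evolution (base frequencies
   A 0.30 / C 0.20 / G 0.15 / T 0.35, transition/transversion ratio 2.5),
   rejection-sampled so the suite hits exact segregating-site targets
   S ∈ {5, 10, 15, 20, 25, 30, 35}, five replicates each (35 datasets).
2. **Genotype collapse** — each simulated allele pair is collapsed to a
   consensus with IUPAC ambiguity codes, discarding phase.
3. **Phasing** — a built-in Gibbs sampler with a coalescent-flavored
   conditional haplotype prior (3 replicate chains of 500 burn-in + 500 main
   iterations; the best-goodness replicate is kept), plus a writer for the
   standard external phasing input format.
4. **Scoring** — resolved/unresolved partition at confidence thresholds 0.90
   and 0.60; an error taxonomy over confident calls (correct / five error
   classes by whether each inferred haplotype is correct, miscalled-known, or
   novel); lost-allele counts; genotypic configurations; divergence skew of
   lost alleles.
5. **Bias measurement** — Watterson's Θ<sub>W</sub>, π, Tajima's D and Fu's
   F<sub>S</sub> before and after pruning unresolved individuals, with paired
   one-tailed t-tests and OLS regressions.
6. **Networks** — statistical-parsimony haplotype networks with a 95%
   connection limit and outgroup-weight rooting, comparing root identity and
   component structure before and after pruning.

## Quick start

```sh
# regenerate the 35-dataset benchmark suite as FASTA + truth tables
phasebias simulate --seed 1 --outdir datasets/

# phase one dataset's consensus genotypes
phasebias phase --consensus datasets/Sim01_consensus.fasta \
    --out Sim01_phased.tsv --seed 7

# run the whole study and write a pooled summary
phasebias run-all --seed 1 --out results/summary.json
```

Or from Python:

```python
from phasebias.pipeline import run_study
from phasebias.simulate import SimulationConfig
from phasebias.phasing import PhasingRunConfig

study = run_study(SimulationConfig(seed=1), PhasingRunConfig(), seed=2024)
print(study.pooled_error_rate(0.90))
print(study.original_means())
```

## What the benchmark shows

One full run (simulation seed 1, phasing seed 2024) gives, pooled over the
1101 ambiguous genotypes in the 35 datasets:

| threshold | confident errors | unresolved (N_LCP) | unresolved yet correct | lost alleles |
|-----------|-----------------:|-------------------:|-----------------------:|-------------:|
| 0.90      | 0 (0.00%)        | 462                | 395                    | 187          |
| 0.60      | 2 (0.18%)        | 163                | 98                     | 126          |

The phase-known suite recovers the expected neutral behaviour: mean per-site
π ≈ 0.016, mean Tajima's D ≈ 0.09 ± 0.14, mean Fu's F<sub>S</sub> ≈ −0.05 ±
0.54. After pruning unresolved individuals the four statistics shift in a
consistent direction — Θ<sub>W</sub> and π decrease, D and F<sub>S</sub>
increase — in ≥ 79% of affected datasets at the 0.90 threshold and in 100% at
0.60. A minority of datasets (2 of 34 with any pruning) also change their
network root or split the root's network component.

The headline caution this reproduces: discarding below-threshold genotypes is
not a conservative choice. The discarded individuals are enriched for rare
and divergent alleles, so "playing it safe" biases diversity down and
neutrality statistics up.

## Layout

- `src/phasebias/simulate.py` — coalescent + HKY85 generator, consensus collapse
- `src/phasebias/phasing.py` — Gibbs phasing engine and replicate protocol
- `src/phasebias/popgen.py` — S, A_N, G_N, H_O, Θ_W, π, Tajima's D, Fu's F_S
- `src/phasebias/evaluate.py` — error taxonomy, lost alleles, divergence skew
- `src/phasebias/bias.py` — pruning and paired statistical comparisons
- `src/phasebias/network.py` — parsimony networks and rooting
- `src/phasebias/formats.py` — FASTA / phaser-input / TSV I/O, indel recoding
- `src/phasebias/reference.py` + `data/` — published benchmark characteristics
- `src/phasebias/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — model details and design decisions

## Testing and reproduction

```sh
python -m pytest -q tests/            # full suite (~5 min; phases all 35 datasets once)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` regenerates the suite, phases it, and writes the
pooled 0.90-threshold error rate plus the three neutral-statistic means as
JSON. All randomness derives from `--seed`; the same seed reproduces the same
numbers exactly.
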