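"""Sampler correctness: enumeration, exact-posterior agreement, protocol."""

import numpy as np
import pytest

from phasebias.phasing import (
    PhasingRunConfig,
    apply_confidence_threshold,
    enumerate_pair_candidates,
    genotype_from_consensus,
    gibbs_phase,
    phase_dataset,
    select_best_replicate,
)
from phasebias.popgen import harmonic_number
from phasebias.simulate import AmbiguousGenotype, SimulationConfig, generate_suite


def test_consensus_parser_flags_invalid_codes_with_position():
    g = genotype_from_consensus("x", "ARYT")
    assert g.het_positions == (1, 2)
    with pytest.raises(ValueError, match="position 3"):
        genotype_from_consensus("x", "AAXA")


def test_pair_enumeration_counts_and_collapses_back():
    g = genotype_from_consensus("x", "RAYW")  # het at 0, 2, 3
    pairs = enumerate_pair_candidates(g)
    assert len(pairs) == 4  # 2^(h-1) distinct unordered decompositions
    assert len(set(pairs)) == 4
    from phasebias.simulate import collapse_to_consensus

    for a, b in pairs:
        cons, _ = collapse_to_consensus(a, b)
        assert cons == g.consensus


def test_pair_enumeration_respects_cap():
    g = genotype_from_consensus("x", "R" * 25)
    with pytest.raises(ValueError, match="cap"):
        enumerate_pair_candidates(g, cap=20)


def _toy_genotypes():
    # One 2-site heterozygote among five homozygotes covering both
    # candidate decompositions at different pool frequencies.
    return [
        AmbiguousGenotype("i0", "RAYA", (0, 2)),
        AmbiguousGenotype("i1", "AACA", ()),
        AmbiguousGenotype("i2", "AACA", ()),
        AmbiguousGenotype("i3", "GATA", ()),
        AmbiguousGenotype("i4", "AATA", ()),
        AmbiguousGenotype("i5", "GACA", ()),
    ]


def _exact_posterior(genotypes, config):
    """Independent enumeration of the single ambiguous individual's posterior."""
    pool = []
    for g in genotypes[1:]:
        pool += [g.consensus, g.consensus]
    n = 2 * len(genotypes)
    var_cols = (0, 2)
    theta = len(var_cols) / harmonic_number(n - 1)
    rho = theta / (theta + n)
    d_cap = config.kernel_steps
    eps = rho ** (d_cap + 1)

    def dist(x, y):
        return sum(x[c] != y[c] for c in var_cols)

    def pi(x):
        return sum(rho ** dist(x, y) for y in pool if dist(x, y) <= d_cap)

    cross = rho**2 if 2 <= d_cap else 0.0
    scores = {
        (a, b): (pi(a) + eps) * (pi(b) + cross + eps)
        for a, b in enumerate_pair_candidates(genotypes[0])
    }
    z = sum(scores.values())
    return {p: s / z for p, s in scores.items()}


def test_sampled_posterior_matches_enumeration_oracle():
    genotypes = _toy_genotypes()
    config = PhasingRunConfig(burn_in=200, main_iters=4000, n_replicates=1)
    exact = _exact_posterior(genotypes, config)
    result = gibbs_phase(genotypes, config, seed=42)
    post = result.posteriors["i0"]
    for pair, p in exact.items():
        sampled = post.candidates.get(pair, 0.0)
        se = np.sqrt(p * (1 - p) / config.main_iters)
        assert abs(sampled - p) <= 3 * se + 1e-12


def test_phase_trivial_individuals_get_unit_confidence():
    genotypes = _toy_genotypes()
    result = gibbs_phase(genotypes, PhasingRunConfig(burn_in=10, main_iters=20), 3)
    for ind in ("i1", "i3"):
        post = result.posteriors[ind]
        assert post.best_prob == 1.0
        assert post.best_pair == (
            genotypes[int(ind[1])].consensus,
            genotypes[int(ind[1])].consensus,
        )
    assert result.ambiguous_ids == ("i0",)


def test_replicate_protocol_is_reproducible():
    genotypes = _toy_genotypes()
    config = PhasingRunConfig(burn_in=50, main_iters=100)
    best1, reps1 = phase_dataset(genotypes, config, seed=7)
    best2, reps2 = phase_dataset(genotypes, config, seed=7)
    assert best1.posteriors["i0"].candidates == best2.posteriors["i0"].candidates
    assert [r.seed for r in reps1] == [r.seed for r in reps2]
    assert len(reps1) == config.n_replicates
    assert best1.selected


def test_best_replicate_selection_prefers_goodness_then_low_seed():
    from phasebias.phasing import PairPosterior, PhasingResult

    def rep(seed, goodness):
        post = PairPosterior("i0", {("A", "T"): 1.0}, ("A", "T"), 1.0)
        return PhasingResult({"i0": post}, seed, goodness, ("i0",))

    picked = select_best_replicate([rep(3, 0.5), rep(2, 0.9), rep(1, 0.9)])
    assert picked.seed == 1


def test_confidence_threshold_boundary_counts_as_resolved():
    from phasebias.phasing import PairPosterior, PhasingResult

    post = PairPosterior("i0", {("A", "T"): 0.9, ("C", "G"): 0.1}, ("A", "T"), 0.9)
    res = PhasingResult({"i0": post}, 1, 0.9, ("i0",))
    part = apply_confidence_threshold(res, 0.9)
    assert "i0" in part.resolved and not part.unresolved
    part = apply_confidence_threshold(res, 0.901)
    assert "i0" in part.unresolved


def test_scaffolded_alleles_phase_to_high_accuracy():
    # When every allele carried by an ambiguous genotype also occurs in a
    # phase-trivial individual, the sampler should recover truth confidently.
    ds = generate_suite(
        SimulationConfig(seed=3, s_targets=(5,), replicates_per_target=1)
    )[0]
    best, _ = phase_dataset(ds.genotypes, PhasingRunConfig(), seed=5)
    correct = 0
    scored = 0
    for ind_id in best.ambiguous_ids:
        scored += 1
        if best.posteriors[ind_id].best_pair == ds.true_pair(ind_id):
            correct += 1
    assert scored > 0
    assert correct / scored >= 0.8
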