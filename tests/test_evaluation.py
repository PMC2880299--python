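"""Error taxonomy, lost alleles, configurations, divergence skew."""

import pytest

from phasebias.evaluate import (
    ErrorClass,
    classify_error,
    configuration_profile,
    divergence_skew,
    evaluate_dataset,
    find_lost_alleles,
    het_error_relationship,
    pooled_error_rate,
)
from phasebias.phasing import PairPosterior, ThresholdedResult

KNOWN = {"AAA", "AAT", "ATT", "TTT"}


def test_correct_pair_is_correct_in_either_order():
    assert classify_error(("AAA", "AAT"), ("AAT", "AAA"), KNOWN) is ErrorClass.CORRECT


def test_error_classes_cover_all_mistake_shapes():
    true = ("AAA", "ATT")
    assert classify_error(true, ("AAA", "GGG"), KNOWN) is ErrorClass.E_COR_NOV
    assert classify_error(true, ("AAA", "TTT"), KNOWN) is ErrorClass.E_COR_MIS
    assert classify_error(true, ("AAT", "TTT"), KNOWN) is ErrorClass.E_MIS_MIS
    assert classify_error(true, ("AAT", "GGG"), KNOWN) is ErrorClass.E_MIS_NOV
    assert classify_error(true, ("GGG", "CCC"), KNOWN) is ErrorClass.E_NOV_NOV
    # duplicating one true haplotype uses the mixed correct/mis class
    assert classify_error(true, ("AAA", "AAA"), KNOWN) is ErrorClass.E_COR_MIS


def test_complement_consistent_pairs_never_hit_cor_star_classes(make_truth):
    # A pair that collapses back to the genotype shares every homozygous
    # site with the truth, so a single correct haplotype forces the other
    # to be correct too: only CORRECT, E_MIS+MIS, E_MIS+NOV, E_NOV+NOV.
    from phasebias.phasing import enumerate_pair_candidates
    from phasebias.simulate import collapse_to_consensus

    truth = make_truth([("AACCA", "ATCTA"), ("AACCA", "AACCA"), ("ATCTA", "ATCTA"),
                        ("AACTA", "ATCCA")])
    known = set(truth.alignment.sequences)
    for g in truth.genotypes:
        if not g.is_ambiguous:
            continue
        for pair in enumerate_pair_candidates(g):
            cons, _ = collapse_to_consensus(*pair)
            assert cons == g.consensus
            cls = classify_error(truth.true_pair(g.individual_id), pair, known)
            assert cls in {
                ErrorClass.CORRECT,
                ErrorClass.E_MIS_MIS,
                ErrorClass.E_MIS_NOV,
                ErrorClass.E_NOV_NOV,
            }


def test_lost_alleles_require_every_carrier_unresolved(make_truth):
    truth = make_truth([("AAT", "ATA"), ("AAT", "AAA"), ("AAA", "AAA")])
    # allele ATA is carried only by ind000; AAT by ind000 and ind001
    n_lost, lost = find_lost_alleles(truth, ["ind000"])
    assert n_lost == 1 and lost == ["ATA"]
    n_lost, lost = find_lost_alleles(truth, ["ind000", "ind001"])
    assert set(lost) == {"ATA", "AAT"}
    with pytest.raises(ValueError):
        find_lost_alleles(truth, ["nobody"])


def _partition(truth, resolved_pairs, unresolved_pairs, threshold=0.9):
    resolved = {
        i: PairPosterior(i, {p: 0.95}, p, 0.95) for i, p in resolved_pairs.items()
    }
    unresolved = {
        i: PairPosterior(i, {p: 0.5}, p, 0.5) for i, p in unresolved_pairs.items()
    }
    return ThresholdedResult(threshold, resolved, unresolved)


def test_dataset_evaluation_counts_errors_and_unresolved(make_truth):
    truth = make_truth(
        [("AACC", "ATCA"), ("AACA", "ATCC"), ("AACC", "AACC"), ("ATCA", "ATCA")]
    )
    part = _partition(
        truth,
        {"ind000": ("AACC", "ATCA"), "ind001": ("AACC", "ATCA")},
        {},
    )
    summary = evaluate_dataset(truth, part)
    assert summary.n_ambiguous == 2
    assert summary.n_err == 1  # ind001's true pair differs
    assert summary.err_classes[ErrorClass.E_MIS_MIS] == 1
    assert summary.n_lcp == 0

    part = _partition(truth, {}, {"ind000": ("AACC", "ATCA"),
                                  "ind001": ("AACA", "ATCC")})
    summary = evaluate_dataset(truth, part)
    assert summary.n_err == 0
    assert summary.n_lcp == 2
    assert summary.n_lcp_correct == 2
    assert summary.proportion_unresolved == pytest.approx(1.0)


def test_genotypic_configuration_profile_flags_rarity(make_truth):
    pairs = [("AAT", "ATA")] + [("AAA", "AAA")] * 20
    truth = make_truth(pairs)
    profile = configuration_profile(truth, ["ind000", "ind001"])
    by_id = {r.individual_id: r for r in profile}
    rec = by_id["ind000"]
    assert rec.both_rare  # AAT and ATA are both singletons among 42 copies
    assert rec.rare_is_singleton
    common = by_id["ind001"]
    assert not common.both_rare
    assert not common.rare_is_singleton


def test_divergence_skew_sign_and_hand_values(make_truth):
    truth = make_truth([("AAAA", "AAAT"), ("AAAA", "AAAA"), ("TTTT", "AAAA")])
    skew = divergence_skew(truth, ["TTTT"])
    # distinct alleles: AAAA, AAAT, TTTT; p(TTTT to others) = (1 + 0.75)/2
    assert skew.p_lost[0] == pytest.approx((1 + 0.75) / 2)
    assert skew.p_dataset == pytest.approx((0.25 + 1 + 0.75) / 3)
    assert skew.difference == pytest.approx(0.875 - 2 / 3)
    assert divergence_skew(truth, []) is None


def test_heterozygosity_error_relationship_requires_three_classes():
    assert het_error_relationship([(2, False), (3, True)]) is None
    r = het_error_relationship(
        [(2, False), (2, False), (3, False), (3, True), (4, True), (4, True)]
    )
    assert r == pytest.approx(1.0, abs=1e-9)


def test_pooled_error_rate_matches_published_arithmetic():
    assert round(pooled_error_rate(5, 1077), 1) == 0.5
    assert round(pooled_error_rate(9, 1077), 1) == 0.8
    with pytest.raises(ValueError):
        pooled_error_rate(1, 0)
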