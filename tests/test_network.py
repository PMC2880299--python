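"""Parsimony networks: connection limit, construction, rooting, comparisons."""

import pytest

from phasebias.network import (
    build_networks,
    compare_roots,
    dataset_root,
    outgroup_weights,
    parsimony_connection_limit,
    parsimony_probability,
    root_by_outgroup_weight,
)


def test_parsimony_probability_boundaries_and_monotonicity():
    assert parsimony_probability(0, 250) == 1.0
    probs = [parsimony_probability(j, 250) for j in range(1, 20)]
    assert all(a > b for a, b in zip(probs, probs[1:]))
    assert parsimony_probability(200, 250) == 0.0
    with pytest.raises(ValueError):
        parsimony_probability(-1, 250)


def test_connection_limit_sits_exactly_at_the_confidence_boundary():
    limit = parsimony_connection_limit(250, 0.95)
    assert limit >= 1
    assert parsimony_probability(limit, 250) >= 0.95
    assert parsimony_probability(limit + 1, 250) < 0.95
    # longer loci admit more steps at the same confidence
    assert parsimony_connection_limit(1000, 0.95) > limit


def test_networks_link_single_steps_without_intermediates():
    nets = build_networks({"AAAAA": 6, "AAAAT": 2, "AAATT": 1}, limit=1)
    assert len(nets) == 1
    net = nets[0]
    assert sorted(net.observed_nodes) == ["H01", "H02", "H03"]
    assert net.graph.number_of_edges() == 2
    assert net.total_frequency == 9
    # label order follows decreasing frequency
    assert net.sequence("H01") == "AAAAA"


def test_multi_step_links_insert_unobserved_intermediates():
    [net] = build_networks({"AAAAA": 3, "AAATT": 1}, limit=2)
    unobserved = [
        n for n, d in net.graph.nodes(data=True) if not d["observed"]
    ]
    assert len(unobserved) == 1
    assert net.graph.degree[unobserved[0]] == 2
    assert net.graph.number_of_edges() == 2


def test_haplotypes_beyond_the_limit_stay_disconnected():
    nets = build_networks({"AAAAA": 2, "TTTTT": 2}, limit=2)
    assert len(nets) == 2
    assert all(len(net.observed_nodes) == 1 for net in nets)


def test_network_construction_is_deterministic():
    haps = {"AAAAA": 3, "AAAAT": 2, "AATAT": 1, "TTTTT": 4}
    a = build_networks(haps, limit=2)
    b = build_networks(haps, limit=2)
    assert [sorted(net.graph.nodes) for net in a] == [
        sorted(net.graph.nodes) for net in b
    ]
    assert [sorted(net.graph.edges) for net in a] == [
        sorted(net.graph.edges) for net in b
    ]


def test_outgroup_weights_normalize_and_favor_frequent_central_haplotypes():
    star = {
        "AAAAA": 10,
        "TAAAA": 1,
        "ATAAA": 1,
        "AATAA": 1,
        "AAATA": 1,
    }
    [net] = build_networks(star, limit=1)
    weights = outgroup_weights(net)
    assert sum(weights.values()) == pytest.approx(1.0)
    root = root_by_outgroup_weight(net)
    assert net.sequence(root) == "AAAAA"
    # hand computation: centre weight (10/14)/(1+1), each tip
    # (1/14)/(1 + (1+2+2+2)/4)
    centre_raw = (10 / 14) / 2
    tip_raw = (1 / 14) / 2.75
    assert weights[root] == pytest.approx(centre_raw / (centre_raw + 4 * tip_raw))


def test_dataset_root_weighs_networks_by_their_sample_share():
    nets = build_networks({"AAAAA": 8, "AAAAT": 1, "TTTTT": 2}, limit=1)
    node, seq = dataset_root(nets)
    assert seq == "AAAAA"
    with pytest.raises(ValueError):
        dataset_root([])


def test_root_comparison_flags_root_turnover():
    original = build_networks({"AAAAA": 6, "AAAAT": 2}, limit=1)
    pruned = build_networks({"AAAAT": 2}, limit=1)
    cmp = compare_roots(original, pruned)
    assert cmp.changed
    assert cmp.original_root == "AAAAA"
    assert cmp.pruned_root == "AAAAT"


def test_root_comparison_flags_component_splits_around_the_root():
    original = build_networks({"AAAAA": 4, "AAAAT": 2, "AAATT": 1}, limit=1)
    # losing the intermediate haplotype strands the root from AAATT
    pruned = build_networks({"AAAAA": 4, "AAATT": 1}, limit=1)
    cmp = compare_roots(original, pruned)
    assert cmp.original_root == cmp.pruned_root == "AAAAA"
    assert cmp.components_before == 1
    assert cmp.components_after == 2
    assert cmp.changed


def test_root_comparison_is_quiet_when_nothing_qualitative_moves():
    original = build_networks({"AAAAA": 6, "AAAAT": 2}, limit=1)
    pruned = build_networks({"AAAAA": 5, "AAAAT": 2}, limit=1)
    cmp = compare_roots(original, pruned)
    assert not cmp.changed
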