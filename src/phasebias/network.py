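"""Statistical-parsimony haplotype networks with outgroup-weight rooting.

Distinct haplotypes are linked by single mutational steps, in increasing order
of pairwise distance, up to a connection limit: the largest number of steps
whose probability of parsimony (no superimposed change hiding extra steps)
still meets a confidence criterion, conventionally 95%.  Links longer than one
step insert unobserved intermediate haplotypes.  Haplotypes that cannot be
joined within the limit form separate networks.

The parsimony probability is evaluated under a per-site Poisson substitution
model: for two sequences differing at j of L sites, the per-site substitution
load lambda is the Jukes-Cantor estimate -3/4 ln(1 - 4j/(3L)); a differing
site is parsimonious (exactly one change) with probability
lambda e^-lambda / ((3/4)(1 - e^(-4 lambda / 3))), and the j-step parsimony
probability is that quantity to the j-th power.  Root probabilities use a
surrogate outgroup weight combining sample frequency with topological
centrality: weight proportional to relative frequency divided by (1 + mean
graph distance to the other observed haplotypes in the network); the rooting
comparisons downstream are qualitative (changed / not changed, component
counts), so the weight formula is isolated here for substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "HaplotypeNetwork",
    "RootComparison",
    "parsimony_probability",
    "parsimony_connection_limit",
    "build_networks",
    "root_by_outgroup_weight",
    "dataset_root",
    "compare_roots",
]


def parsimony_probability(j: int, length: int) -> float:
    """Probability that j observed differences over ``length`` sites involve
    no superimposed substitutions (each differing site changed exactly once)."""
    if j < 0:
        raise ValueError("negative step count")
    if j == 0:
        return 1.0
    frac = 4 * j / (3 * length)
    if frac >= 1:
        return 0.0
    lam = -0.75 * math.log(1 - frac)
    p_diff = 0.75 * (1 - math.exp(-4 * lam / 3))
    p_single = lam * math.exp(-lam) / p_diff
    return p_single**j


def parsimony_connection_limit(length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability meets the confidence level."""
    if length < 1:
        raise ValueError("length must be positive")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    limit = 0
    j = 1
    while j < length and parsimony_probability(j, length) >= confidence:
        limit = j
        j += 1
    return limit


@dataclass
class HaplotypeNetwork:
    """One connected parsimony network.

    ``graph`` nodes are haplotype labels; observed nodes carry ``sequence``
    and ``frequency`` attributes (frequency = number of sampled allele
    copies), inferred intermediates carry ``observed=False``.  Every edge
    spans exactly one mutational step.
    """

    graph: nx.Graph

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    def frequency(self, node: str) -> int:
        return self.graph.nodes[node]["frequency"]

    def sequence(self, node: str) -> str:
        return self.graph.nodes[node]["sequence"]

    @property
    def total_frequency(self) -> int:
        return sum(self.frequency(n) for n in self.observed_nodes)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_networks(
    haplotypes: dict[str, int], limit: int
) -> list[HaplotypeNetwork]:
    """Link distinct haplotypes (sequence -> sampled frequency) into networks.

    Pairs are joined agglomeratively in increasing pairwise-distance order
    (ties broken lexicographically for determinism); pairs beyond the
    connection limit are never joined, so the result may be several disjoint
    networks.  A d-step link inserts d-1 unobserved intermediate nodes.
    """
    seqs = sorted(haplotypes)
    if not seqs:
        return []
    g = nx.Graph()
    labels = {}
    for k, seq in enumerate(sorted(seqs, key=lambda s: (-haplotypes[s], s))):
        label = f"H{k + 1:02d}"
        labels[seq] = label
        g.add_node(label, sequence=seq, frequency=haplotypes[seq], observed=True)

    pairs = []
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            d = _hamming(a, b)
            if 0 < d <= limit:
                pairs.append((d, labels[a], labels[b]))
    pairs.sort()

    comp = {labels[s]: labels[s] for s in seqs}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    n_inter = 0
    for d, a, b in pairs:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        comp[ra] = rb
        chain = [a]
        for _ in range(d - 1):
            n_inter += 1
            node = f"i{n_inter:03d}"
            g.add_node(node, observed=False, sequence=None, frequency=0)
            chain.append(node)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v)

    return [
        HaplotypeNetwork(g.subgraph(c).copy())
        for c in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ]


def outgroup_weights(network: HaplotypeNetwork) -> dict[str, float]:
    """Normalized root probabilities of the observed haplotypes in one network.

    Weight proportional to relative sample frequency times
    1 / (1 + mean graph distance to the other observed haplotypes).
    """
    obs = network.observed_nodes
    if not obs:
        raise ValueError("network has no observed haplotypes")
    total = network.total_frequency
    raw = {}
    for node in obs:
        if len(obs) > 1:
            dists = [
                nx.shortest_path_length(network.graph, node, other)
                for other in obs
                if other != node
            ]
            centrality = 1.0 / (1.0 + float(np.mean(dists)))
        else:
            centrality = 1.0
        raw[node] = network.frequency(node) / total * centrality
    z = sum(raw.values())
    return {n: w / z for n, w in raw.items()}


def root_by_outgroup_weight(network: HaplotypeNetwork) -> str:
    """Observed haplotype with the highest outgroup weight in one network.

    Ties break towards higher frequency, then lexicographically smaller
    sequence, so the choice is deterministic.
    """
    weights = outgroup_weights(network)
    return min(
        weights,
        key=lambda n: (-weights[n], -network.frequency(n), network.sequence(n)),
    )


def dataset_root(networks: Sequence[HaplotypeNetwork]) -> tuple[str, str]:
    """Dataset-level root: the highest-weight haplotype across all networks.

    Per-network weights are scaled by the network's share of sampled allele
    copies.  Returns (node label, sequence).
    """
    if not networks:
        raise ValueError("no networks supplied")
    grand_total = sum(net.total_frequency for net in networks)
    candidates = []
    for net in networks:
        share = net.total_frequency / grand_total
        for node, w in outgroup_weights(net).items():
            candidates.append(
                (-w * share, -net.frequency(node), net.sequence(node), node)
            )
    _, _, seq, node = min(candidates)
    return node, seq


@dataclass
class RootComparison:
    """Root and component changes between original and pruned networks."""

    original_root: str            # sequence
    pruned_root: str              # sequence
    components_before: int
    components_after: int
    changed: bool


def compare_roots(
    original: Sequence[HaplotypeNetwork],
    pruned: Sequence[HaplotypeNetwork],
) -> RootComparison:
    """Flag root-identity and component changes caused by pruning.

    ``changed`` is true when the dataset root sequence differs, or when the
    component membership of the original root changed: the set of surviving
    haplotypes sharing a network with it is no longer the same.
    """
    _, orig_root_seq = dataset_root(original)
    _, pruned_root_seq = dataset_root(pruned)
    changed = orig_root_seq != pruned_root_seq

    surviving = {
        net.sequence(n) for net in pruned for n in net.observed_nodes
    }

    def companions(
        networks: Sequence[HaplotypeNetwork], seq: str
    ) -> Optional[frozenset]:
        for net in networks:
            seqs = {net.sequence(n) for n in net.observed_nodes}
            if seq in seqs:
                return frozenset(seqs & surviving)
        return None

    before = companions(original, orig_root_seq)
    after = companions(pruned, orig_root_seq)
    if before is not None and before != after:
        changed = True
    return RootComparison(
        original_root=orig_root_seq,
        pruned_root=pruned_root_seq,
        components_before=len(original),
        components_after=len(pruned),
        changed=changed,
    )
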