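"""Shared fixtures: a session-scoped benchmark study and a truth-set factory."""

from __future__ import annotations

import pytest

from phasebias.phasing import PhasingRunConfig
from phasebias.pipeline import StudyResult, run_study
from phasebias.popgen import summarize_polymorphism
from phasebias.simulate import (
    AlleleAlignment,
    AmbiguousGenotype,
    DiploidIndividual,
    SimulationConfig,
    TruthDataset,
    collapse_to_consensus,
)


@pytest.fixture(scope="session")
def benchmark_study() -> StudyResult:
    """The regenerated 35-dataset suite, phased with the replicate protocol.

    Shared across the stochastic acceptance-style tests so the expensive
    simulate-and-phase pass runs once per session.
    """
    return run_study(
        SimulationConfig(seed=1),
        PhasingRunConfig(),
        seed=2024,
        with_networks=False,
    )


@pytest.fixture()
def make_truth():
    """Factory building a phase-known dataset from explicit allele pairs."""

    def _make(seq_pairs: list[tuple[str, str]], label: str = "toy") -> TruthDataset:
        ids: list[str] = []
        seqs: list[str] = []
        individuals: list[DiploidIndividual] = []
        genotypes: list[AmbiguousGenotype] = []
        for k, (a, b) in enumerate(seq_pairs):
            ia, ib = f"ind{k:03d}_a", f"ind{k:03d}_b"
            ids += [ia, ib]
            seqs += [a, b]
            individuals.append(DiploidIndividual(f"ind{k:03d}", ia, ib))
            cons, hets = collapse_to_consensus(a, b)
            genotypes.append(AmbiguousGenotype(f"ind{k:03d}", cons, hets))
        alignment = AlleleAlignment(ids=ids, sequences=seqs)
        summary = summarize_polymorphism(
            seqs, [(2 * k, 2 * k + 1) for k in range(len(seq_pairs))]
        )
        return TruthDataset(
            alignment=alignment,
            individuals=individuals,
            genotypes=genotypes,
            summary=summary,
            seed=0,
            scaling=1e-6,
            label=label,
        )

    return _make
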