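"""End-to-end study orchestration: simulate, phase, evaluate, measure bias.

``run_study`` regenerates a conditioned dataset suite, phases every dataset
with the replicate protocol, partitions ambiguous genotypes at each confidence
threshold, scores errors and lost alleles against the phase-known truth,
recomputes the four phylogeographic statistics on pruned datasets, and
(optionally) compares haplotype-network roots before and after pruning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from phasebias.bias import BiasRecord, compute_bias_table, prune_unresolved
from phasebias.evaluate import EvalSummary, evaluate_dataset
from phasebias.network import (
    RootComparison,
    build_networks,
    compare_roots,
    parsimony_connection_limit,
)
from phasebias.phasing import (
    PhasingResult,
    PhasingRunConfig,
    ThresholdedResult,
    apply_confidence_threshold,
    phase_dataset,
)
from phasebias.popgen import PopGenSummary
from phasebias.simulate import SimulationConfig, TruthDataset, generate_suite

__all__ = ["DatasetResult", "StudyResult", "run_study", "phase_and_evaluate"]


@dataclass
class DatasetResult:
    """Everything computed for one dataset."""

    dataset: TruthDataset
    phasing: PhasingResult
    thresholded: dict[float, ThresholdedResult]
    evals: dict[float, EvalSummary]
    pruned_summaries: dict[float, Optional[PopGenSummary]]
    root_comparisons: dict[float, Optional[RootComparison]] = field(
        default_factory=dict
    )


@dataclass
class StudyResult:
    """Suite-level results with pooled summaries."""

    results: list[DatasetResult]
    sim_config: SimulationConfig
    phasing_config: PhasingRunConfig

    def pooled_error_rate(self, threshold: float) -> float:
        """Above-threshold errors per 100 pooled ambiguous genotypes."""
        n_err = sum(r.evals[threshold].n_err for r in self.results)
        n_amb = sum(r.evals[threshold].n_ambiguous for r in self.results)
        return 100.0 * n_err / n_amb if n_amb else 0.0

    def pooled_ambiguous(self) -> int:
        return sum(r.dataset.n_ambiguous for r in self.results)

    def original_means(self) -> dict[str, float]:
        """Mean per-site theta_W and pi, Tajima's D and Fu's F_S over the
        phase-known datasets (undefined values excluded)."""
        out = {}
        for key, attr in [
            ("theta_w_site", "theta_w_site"),
            ("pi_site", "pi_site"),
            ("tajima_d", "tajima_d"),
            ("fu_fs", "fu_fs"),
        ]:
            vals = [
                getattr(r.dataset.summary, attr)
                for r in self.results
                if getattr(r.dataset.summary, attr) is not None
            ]
            out[key] = float(np.mean(vals))
            out[key + "_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        return out

    def bias_records(self, threshold: float) -> list[BiasRecord]:
        entries = []
        for r in self.results:
            pruned = r.pruned_summaries[threshold]
            if pruned is None:
                continue
            entries.append(
                (
                    r.dataset.label,
                    threshold,
                    r.evals[threshold].n_lcp,
                    r.dataset.summary,
                    pruned,
                )
            )
        return compute_bias_table(entries)


def phase_and_evaluate(
    dataset: TruthDataset,
    phasing_config: PhasingRunConfig,
    seed: int,
    with_networks: bool = False,
) -> DatasetResult:
    """Phase one dataset and score it at every configured threshold."""
    best, _ = phase_dataset(dataset.genotypes, phasing_config, seed)
    thresholded: dict[float, ThresholdedResult] = {}
    evals: dict[float, EvalSummary] = {}
    pruned_summaries: dict[float, Optional[PopGenSummary]] = {}
    root_comparisons: dict[float, Optional[RootComparison]] = {}

    limit = None
    original_networks = None
    if with_networks:
        limit = parsimony_connection_limit(dataset.alignment.length)
        original_networks = build_networks(
            dict(Counter(dataset.alignment.sequences)), limit
        )

    for threshold in phasing_config.thresholds:
        part = apply_confidence_threshold(best, threshold)
        thresholded[threshold] = part
        evals[threshold] = evaluate_dataset(dataset, part)
        try:
            pruned = prune_unresolved(dataset, part.unresolved_ids)
            pruned_summaries[threshold] = pruned.summary
        except ValueError:
            pruned = None
            pruned_summaries[threshold] = None
        if with_networks and pruned is not None and part.unresolved_ids:
            pruned_networks = build_networks(
                dict(Counter(pruned.alignment.sequences)), limit
            )
            root_comparisons[threshold] = compare_roots(
                original_networks, pruned_networks
            )
        else:
            root_comparisons[threshold] = None

    return DatasetResult(
        dataset=dataset,
        phasing=best,
        thresholded=thresholded,
        evals=evals,
        pruned_summaries=pruned_summaries,
        root_comparisons=root_comparisons,
    )


def run_study(
    sim_config: SimulationConfig,
    phasing_config: PhasingRunConfig,
    seed: int,
    with_networks: bool = False,
) -> StudyResult:
    """Regenerate the suite and run the full phase/evaluate/bias pipeline."""
    suite = generate_suite(sim_config)
    ss = np.random.SeedSequence(seed)
    phase_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(len(suite))
    ]
    results = [
        phase_and_evaluate(ds, phasing_config, phase_seeds[k], with_networks)
        for k, ds in enumerate(suite)
    ]
    return StudyResult(
        results=results, sim_config=sim_config, phasing_config=phasing_config
    )
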