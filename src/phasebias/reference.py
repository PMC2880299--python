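"""Published summary characteristics of the benchmark datasets.

The packaged table records, per dataset, the sample size, the number of
ambiguous (multi-site heterozygous) genotypes, and the four polymorphism
measures (S, A_N, G_N, H_O) for the five experimentally phased Collembola
nuclear loci (per population and pooled per locus) and for the 35-dataset
simulated benchmark suite.  The empirical sequences themselves were never
released, so these summaries are the only empirical inputs the pipeline can
consume; they are used for aggregation checks and for placing regenerated
simulations alongside the published design.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_table",
    "simulated_extremes",
    "pooled_empirical_means",
]


def load_reference_table() -> pd.DataFrame:
    """The packaged dataset-characteristics table as a DataFrame."""
    with resources.files("phasebias.data").joinpath(
        "dataset_characteristics.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def simulated_extremes(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Extremes over the simulated benchmark rows (max A_N, max ambiguous, ...)."""
    t = load_reference_table() if table is None else table
    sim = t[t["kind"] == "simulated"]
    return {
        "max_a_n": int(sim["a_n"].max()),
        "min_a_n": int(sim["a_n"].min()),
        "max_ambiguous": int(sim["ambiguous_genotypes"].max()),
        "min_ambiguous": int(sim["ambiguous_genotypes"].min()),
        "max_g_n": int(sim["g_n"].max()),
    }


def pooled_empirical_means(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Means over the five pooled empirical loci."""
    t = load_reference_table() if table is None else table
    loci = t[t["kind"] == "empirical_locus"]
    return {
        "mean_s": float(loci["s"].mean()),
        "mean_a_n": float(loci["a_n"].mean()),
        "mean_g_n": float(loci["g_n"].mean()),
        "mean_h_o": float(loci["h_o"].mean()),
        "n_loci": int(len(loci)),
    }
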