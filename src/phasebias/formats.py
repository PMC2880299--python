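"""Readers, writers and preprocessing transforms for the pipeline's file formats.

FASTA reading/writing is delegated to Biopython.  All user-facing coordinates
are 1-based inclusive; the internal representation is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phasebias.simulate import (
    AlleleAlignment,
    AmbiguousGenotype,
    DiploidIndividual,
    TruthDataset,
    PAIR_FROM_CODE,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_phase_input",
    "recode_indels",
    "mask_columns",
    "MaskSpec",
    "read_genotype_table",
    "write_genotype_table",
    "write_dataset",
    "suite_manifest",
]


def read_fasta(path: str | Path, aligned: bool = True) -> AlleleAlignment:
    """Read a FASTA file into an alignment.

    Lowercase residues are normalized to uppercase with a warning.  With
    ``aligned=True`` (the default), ragged sequence lengths raise an error
    listing the offending ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if any(s != s.upper() for s in seqs):
        warnings.warn(f"lowercase residues in {path} normalized to uppercase")
        seqs = [s.upper() for s in seqs]
    if aligned:
        length = len(seqs[0])
        ragged = [i for i, s in zip(ids, seqs) if len(s) != length]
        if ragged:
            raise ValueError(f"ragged alignment in {path}: {', '.join(ragged)}")
    return AlleleAlignment(ids=ids, sequences=seqs)


def write_fasta(alignment: AlleleAlignment, path: str | Path) -> None:
    """Write an alignment to FASTA (deterministic, one record per sequence)."""
    records = [
        SeqRecord(Seq(seq), id=aid, description="")
        for aid, seq in zip(alignment.ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def _variable_sites(genotypes: Sequence[AmbiguousGenotype]) -> list[int]:
    length = len(genotypes[0].consensus)
    cols = []
    for col in range(length):
        states = {g.consensus[col] for g in genotypes}
        if len(states) > 1 or any(s in PAIR_FROM_CODE for s in states):
            cols.append(col)
    return cols


def write_phase_input(genotypes: Sequence[AmbiguousGenotype]) -> str:
    """Genotype-format text for an external Bayesian phaser.

    Layout: line 1 = number of individuals; line 2 = number of variable
    sites; line 3 = 'P' followed by 1-based site positions; line 4 = per-site
    type string (S biallelic, M multiallelic, covering recoded indel columns);
    then per individual an id line and two rows of allele states at the
    variable sites (heterozygous ambiguity codes expanded to their two bases).
    """
    if not genotypes:
        raise ValueError("no genotypes to write")
    lengths = {len(g.consensus) for g in genotypes}
    if len(lengths) > 1:
        raise ValueError("genotype consensus sequences differ in length")
    cols = _variable_sites(genotypes)

    site_states: list[set[str]] = [set() for _ in cols]
    rows: list[tuple[str, list[str], list[str]]] = []
    for g in genotypes:
        a_row, b_row = [], []
        for k, col in enumerate(cols):
            code = g.consensus[col]
            if code in PAIR_FROM_CODE:
                a, b = sorted(PAIR_FROM_CODE[code])
            elif code in "ACGT":
                a = b = code
            else:
                raise ValueError(
                    f">2 observed states for {g.individual_id} at position "
                    f"{col + 1}: upstream data corrupt"
                )
            site_states[k].update((a, b))
            a_row.append(a)
            b_row.append(b)
        rows.append((g.individual_id, a_row, b_row))

    types = "".join("S" if len(s) <= 2 else "M" for s in site_states)
    lines = [
        str(len(genotypes)),
        str(len(cols)),
        "P " + " ".join(str(c + 1) for c in cols),
        types,
    ]
    for ind_id, a_row, b_row in rows:
        lines.append(f"#{ind_id}")
        lines.append("".join(a_row))
        lines.append("".join(b_row))
    return "\n".join(lines) + "\n"


def recode_indels(
    alignment: AlleleAlignment,
    presence_letter: str = "A",
    absence_letter: str = "T",
) -> AlleleAlignment:
    """Collapse gap runs to single presence/absence columns.

    A maximal run of contiguous columns containing a gap in any sequence (the
    union of run coordinates across sequences) is one indel event: it is
    replaced by a single column holding ``absence_letter`` for sequences with
    a gap anywhere in the run and ``presence_letter`` otherwise.  Discontiguous
    runs are separate events.  Gap-free columns pass through unchanged.
    """
    seqs = alignment.sequences
    length = alignment.length
    gap_cols = [any(s[c] == "-" for s in seqs) for c in range(length)]

    out = [[] for _ in seqs]
    c = 0
    while c < length:
        if not gap_cols[c]:
            for i, s in enumerate(seqs):
                out[i].append(s[c])
            c += 1
            continue
        start = c
        while c < length and gap_cols[c]:
            c += 1
        for i, s in enumerate(seqs):
            has_gap = "-" in s[start:c]
            out[i].append(absence_letter if has_gap else presence_letter)
    return AlleleAlignment(
        ids=list(alignment.ids), sequences=["".join(row) for row in out]
    )


@dataclass(frozen=True)
class MaskSpec:
    """1-based inclusive column ranges to remove from an alignment."""

    ranges: tuple[tuple[int, int], ...]

    def validate(self, length: int) -> None:
        spans = sorted(self.ranges)
        prev_end = 0
        for lo, hi in spans:
            if lo < 1 or hi > length or lo > hi:
                raise ValueError(f"range {lo}-{hi} outside alignment (1-{length})")
            if lo <= prev_end:
                raise ValueError("overlapping mask ranges")
            prev_end = hi

    def columns(self) -> set[int]:
        """0-based column indices to drop."""
        return {c for lo, hi in self.ranges for c in range(lo - 1, hi)}


def mask_columns(alignment: AlleleAlignment, mask: MaskSpec) -> AlleleAlignment:
    """Remove the masked columns (e.g., a hypervariable region)."""
    mask.validate(alignment.length)
    drop = mask.columns()
    keep = [c for c in range(alignment.length) if c not in drop]
    return AlleleAlignment(
        ids=list(alignment.ids),
        sequences=["".join(s[c] for c in keep) for s in alignment.sequences],
    )


def write_genotype_table(
    individuals: Sequence[DiploidIndividual], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(i.individual_id, i.allele_a, i.allele_b) for i in individuals],
        columns=["individual", "allele_a", "allele_b"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotype_table(
    path: str | Path, alignment: AlleleAlignment | None = None
) -> list[DiploidIndividual]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["individual"].duplicated().any():
        raise ValueError("duplicate individuals in genotype table")
    inds = [
        DiploidIndividual(r.individual, r.allele_a, r.allele_b)
        for r in df.itertuples()
    ]
    if alignment is not None:
        known = set(alignment.ids)
        for ind in inds:
            for aid in (ind.allele_a, ind.allele_b):
                if aid not in known:
                    raise ValueError(f"allele id {aid} not in alignment")
    return inds


def write_dataset(dataset: TruthDataset, outdir: str | Path) -> None:
    """Write one dataset: phase-known FASTA, consensus FASTA, truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = dataset.label or "dataset"
    write_fasta(dataset.alignment, outdir / f"{stem}_alleles.fasta")
    consensus = AlleleAlignment(
        ids=[g.individual_id for g in dataset.genotypes],
        sequences=[g.consensus for g in dataset.genotypes],
    )
    write_fasta(consensus, outdir / f"{stem}_consensus.fasta")
    write_genotype_table(dataset.individuals, outdir / f"{stem}_truth.tsv")


def suite_manifest(datasets: Sequence[TruthDataset]) -> pd.DataFrame:
    """Per-dataset summary table (design columns plus provenance)."""
    rows = []
    for ds in datasets:
        s = ds.summary
        rows.append(
            {
                "dataset": ds.label,
                "n_individuals": len(ds.individuals),
                "ambiguous_genotypes": ds.n_ambiguous,
                "s": s.s,
                "a_n": s.a_n,
                "g_n": s.g_n,
                "h_o": s.h_o,
                "seed": ds.seed,
                "scaling": ds.scaling,
            }
        )
    return pd.DataFrame(rows)


def config_hash(config) -> str:
    """Stable short hash of a dataclass-like config, for manifests."""
    payload = json.dumps(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
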