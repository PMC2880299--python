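"""File formats: FASTA handling, phaser input, indel recoding, masking."""

import pytest

from phasebias.formats import (
    MaskSpec,
    mask_columns,
    read_fasta,
    read_genotype_table,
    recode_indels,
    suite_manifest,
    write_dataset,
    write_fasta,
    write_genotype_table,
    write_phase_input,
)
from phasebias.simulate import AlleleAlignment, AmbiguousGenotype


def test_fasta_round_trip_preserves_ids_and_sequences(tmp_path):
    aln = AlleleAlignment(ids=["a1", "a2"], sequences=["ACGT", "ACCT"])
    path = tmp_path / "x.fasta"
    write_fasta(aln, path)
    back = read_fasta(path)
    assert back.ids == aln.ids
    assert back.sequences == aln.sequences


def test_fasta_reader_normalizes_case_and_rejects_ragged(tmp_path):
    path = tmp_path / "y.fasta"
    path.write_text(">a\nacgt\n>b\nACGT\n")
    with pytest.warns(UserWarning, match="lowercase"):
        aln = read_fasta(path)
    assert aln.sequences == ["ACGT", "ACGT"]

    path.write_text(">a\nACGT\n>b\nAC\n")
    with pytest.raises(ValueError, match="ragged"):
        read_fasta(path)
    with pytest.raises(ValueError, match="no sequences"):
        path.write_text("")
        read_fasta(path)


def test_phaser_input_layout_matches_golden_output():
    genotypes = [
        AmbiguousGenotype("ind1", "ARCT", (1,)),
        AmbiguousGenotype("ind2", "AGCT", ()),
        AmbiguousGenotype("ind3", "AACY", (3,)),
    ]
    text = write_phase_input(genotypes)
    # variable sites are columns 2 and 4 (1-based); heterozygous codes expand
    # to their two bases in sorted order
    assert text == (
        "3\n"
        "2\n"
        "P 2 4\n"
        "SS\n"
        "#ind1\n"
        "AT\n"
        "GT\n"
        "#ind2\n"
        "GT\n"
        "GT\n"
        "#ind3\n"
        "AC\n"
        "AT\n"
    )


def test_phaser_input_rejects_empty_and_ragged_genotypes():
    with pytest.raises(ValueError):
        write_phase_input([])
    with pytest.raises(ValueError):
        write_phase_input(
            [AmbiguousGenotype("a", "ACGT", ()), AmbiguousGenotype("b", "AC", ())]
        )


def test_indel_runs_collapse_to_presence_absence_columns():
    aln = AlleleAlignment(
        ids=["a", "b", "c"],
        sequences=["AC--GT-A", "ACTTGTTA", "AC-TGT-A"],
    )
    out = recode_indels(aln)
    # two separate gap runs (columns 3-4 and column 7, 1-based) each become
    # one presence/absence column
    assert out.sequences == ["ACTGTTA", "ACAGTAA", "ACTGTTA"]
    assert out.length == 7
    assert out.ids == aln.ids


def test_mask_spec_validation_and_column_removal():
    aln = AlleleAlignment(ids=["a"], sequences=["ACGTAC"])
    masked = mask_columns(aln, MaskSpec(ranges=((2, 3), (6, 6))))
    assert masked.sequences == ["ATA"]
    with pytest.raises(ValueError, match="outside"):
        MaskSpec(ranges=((0, 2),)).validate(6)
    with pytest.raises(ValueError, match="overlap"):
        MaskSpec(ranges=((1, 3), (3, 4))).validate(6)


def test_genotype_table_round_trip_and_validation(tmp_path, make_truth):
    truth = make_truth([("AAT", "ATA"), ("AAA", "AAA")])
    path = tmp_path / "g.tsv"
    write_genotype_table(truth.individuals, path)
    back = read_genotype_table(path, truth.alignment)
    assert [i.individual_id for i in back] == ["ind000", "ind001"]
    assert back[0].allele_a == "ind000_a"

    other = AlleleAlignment(ids=["zzz"], sequences=["AAA"])
    with pytest.raises(ValueError, match="not in alignment"):
        read_genotype_table(path, other)


def test_dataset_writer_emits_all_three_files(tmp_path, make_truth):
    truth = make_truth([("AAT", "ATA"), ("AAA", "AAA")], label="Demo")
    write_dataset(truth, tmp_path)
    for suffix in ("alleles.fasta", "consensus.fasta", "truth.tsv"):
        assert (tmp_path / f"Demo_{suffix}").exists()
    cons = read_fasta(tmp_path / "Demo_consensus.fasta")
    assert cons.ids == ["ind000", "ind001"]


def test_suite_manifest_columns_and_rows(make_truth):
    datasets = [make_truth([("AAT", "ATA")], label=f"Sim{k}") for k in (1, 2)]
    df = suite_manifest(datasets)
    assert list(df["dataset"]) == ["Sim1", "Sim2"]
    assert set(df.columns) >= {"s", "a_n", "g_n", "h_o", "ambiguous_genotypes"}
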