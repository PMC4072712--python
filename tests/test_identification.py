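"""PSM/protein-list/FASTA IO and the SEQUEST-style acceptance filters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from membranome import (
    PSM,
    AnalysisConfig,
    assemble_proteins,
    filter_psms,
    read_fasta,
    read_protein_list,
    read_psm_table,
    write_protein_list,
)
from membranome.errors import (
    FormatError,
    MissingColumnError,
    RowParseError,
    ValidationError,
)


def psm(peptide="PEPTIDEK", charge=2, xcorr=3.0, probability=1e-4, acc="P1"):
    return PSM(peptide, charge, xcorr, probability, acc)


class TestReadPsmTable:
    def test_well_formed_rows_parse_in_order(self, psm_tsv):
        path = psm_tsv(
            [
                "PEPTIDEK\t2\t3.1\t0.0001\tP1",
                "MKTAYIAK\t1\t1.8\t0.0002\tP2",
                "GVLKEYGV\t3\t2.9\t0.0005\tP1",
            ]
        )
        psms = read_psm_table(path)
        assert [p.peptide for p in psms] == ["PEPTIDEK", "MKTAYIAK", "GVLKEYGV"]
        assert psms[1].charge == 1 and psms[2].protein_accession == "P1"

    def test_header_only_file_is_empty(self, psm_tsv):
        assert read_psm_table(psm_tsv([])) == []

    def test_bad_charge_cites_line_number(self, psm_tsv):
        path = psm_tsv(["PEPTIDEK\tx\t3.1\t0.0001\tP1"])
        with pytest.raises(RowParseError, match="line 2"):
            read_psm_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\tcharge\txcorr\taccession\n", encoding="utf-8")
        with pytest.raises(MissingColumnError, match="probability"):
            read_psm_table(path)

    def test_dialect_maps_column_names(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text(
            "Sequence\tz\tXCorr\tPep_prob\tReference\n"
            "PEPTIDEK\t2\t3.1\t0.0001\tP1\n",
            encoding="utf-8",
        )
        psms = read_psm_table(
            path,
            dialect={
                "peptide": "Sequence",
                "charge": "z",
                "xcorr": "XCorr",
                "probability": "Pep_prob",
                "accession": "Reference",
            },
        )
        assert len(psms) == 1 and psms[0].xcorr == 3.1


class TestReadProteinList:
    def test_distinct_accessions(self, protein_tsv):
        run = read_protein_list(
            protein_tsv(["P1\talpha\t40.2\t7", "P2\tbeta\t12.0\t2"])
        )
        assert {e.accession for e in run.entries} == {"P1", "P2"}

    def test_duplicate_accession_keeps_max_score(self, protein_tsv):
        run = read_protein_list(
            protein_tsv(["P1\talpha\t12\t2", "P1\talpha\t30\t5"])
        )
        (entry,) = run.entries
        assert entry.sc == 30 and entry.hits == 5

    def test_conflicting_description_warns_and_keeps_first(self, protein_tsv):
        with pytest.warns(UserWarning, match="conflicting"):
            run = read_protein_list(
                protein_tsv(["P1\talpha\t12\t2", "P1\tbeta\t30\t5"])
            )
        assert run.entries[0].description == "alpha"

    def test_negative_score_rejected(self, protein_tsv):
        with pytest.raises(ValidationError, match="negative score"):
            read_protein_list(protein_tsv(["P1\talpha\t-5\t2"]))

    def test_write_read_round_trip(self, protein_tsv, tmp_path):
        run = read_protein_list(
            protein_tsv(["P1\talpha\t40.25\t7", "P2\tbeta\t12.5\t2"])
        )
        out = tmp_path / "rt.tsv"
        write_protein_list(run, out)
        back = read_protein_list(out)
        assert [(e.accession, e.sc, e.hits) for e in back.entries] == [
            (e.accession, e.sc, e.hits) for e in run.entries
        ]


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">P1 some description\nmkt\n", encoding="utf-8")
        assert read_fasta(path) == {"P1": "MKT"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.fasta"
        path.write_text("", encoding="utf-8")
        assert read_fasta(path) == {}

    def test_duplicate_accession_errors(self, tmp_path):
        path = tmp_path / "d.fasta"
        path.write_text(">P1\nMKT\n>P1\nGGG\n", encoding="utf-8")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(path)

    def test_invalid_residue_names_record(self, tmp_path):
        path = tmp_path / "b.fasta"
        path.write_text(">P9\nMKTZ\n", encoding="utf-8")
        with pytest.raises(FormatError, match="P9"):
            read_fasta(path)


class TestFilterPsms:
    @pytest.mark.parametrize(
        "charge,xcorr,prob,kept",
        [
            (1, 1.6, 0.0005, True),  # above the 1+ tier
            (1, 1.5, 0.0005, False),  # strict: at the tier is rejected
            (2, 2.0, 0.0005, False),
            (2, 2.01, 0.0005, True),
            (3, 2.5, 0.0005, False),
            (3, 2.6, 0.0005, True),
            (4, 2.6, 0.0005, True),  # charges above 3 reuse the 2.5 tier
            (1, 3.0, 0.002, False),  # probability cap is inclusive at 0.001
            (1, 3.0, 0.001, True),
        ],
    )
    def test_acceptance_rules(self, config, charge, xcorr, prob, kept):
        result = filter_psms([psm(charge=charge, xcorr=xcorr, probability=prob)], config)
        assert bool(result) is kept

    def test_empty_in_empty_out(self, config):
        assert filter_psms([], config) == []

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 5),
                st.floats(0, 6, allow_nan=False),
                st.floats(0, 0.01, allow_nan=False),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_order_preserving(self, rows):
        config = AnalysisConfig()
        psms = [psm(charge=z, xcorr=x, probability=p) for z, x, p in rows]
        once = filter_psms(psms, config)
        assert filter_psms(once, config) == once
        # order preserved: the kept PSMs appear in input order
        it = iter(psms)
        for kept in once:
            assert any(kept is candidate for candidate in it)


class TestAssembleProteins:
    def test_hand_arithmetic_consensus(self, config):
        psms = [
            psm(peptide="AAAAK", xcorr=2.5),
            psm(peptide="CCCCK", xcorr=3.0),
            psm(peptide="DDDDK", xcorr=4.6),
        ]
        (entry,) = assemble_proteins(psms, config)
        assert entry.sc == pytest.approx(10.1)
        assert entry.hits == 3

    def test_below_consensus_minimum_dropped(self, config):
        psms = [psm(peptide="AAAAK", xcorr=2.5), psm(peptide="CCCCK", xcorr=3.0)]
        assert assemble_proteins(psms, config) == []  # 5.5 < 10

    def test_duplicate_peptide_keeps_max_xcorr(self, config):
        psms = [
            psm(peptide="AAAAK", xcorr=6.0),
            psm(peptide="AAAAK", xcorr=4.0),
            psm(peptide="CCCCK", xcorr=5.0),
        ]
        (entry,) = assemble_proteins(psms, config)
        assert entry.sc == pytest.approx(11.0) and entry.hits == 2

    def test_empty_input(self, config):
        assert assemble_proteins([], config) == []

    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, order):
        config = AnalysisConfig()
        base = [
            psm(peptide=f"PEP{'ACDEFG'[i]}K", xcorr=2.0 + i, acc=f"P{i % 2}")
            for i in range(6)
        ]
        shuffled = [base[i] for i in order]
        key = lambda es: [(e.accession, round(e.sc, 9), e.hits) for e in es]
        assert key(assemble_proteins(shuffled, config)) == key(
            assemble_proteins(base, config)
        )

    def test_retained_entries_satisfy_invariants(self, config, small_dataset):
        from membranome.synth import psms_for_run

        _, runs, sequences, _ = small_dataset
        run = runs["reference"][0]
        psms = filter_psms(psms_for_run(run, sequences, seed=3), config)
        for entry in assemble_proteins(psms, config):
            assert entry.hits >= 1
            assert entry.sc >= config.consensus_min
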