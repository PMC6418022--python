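"""FASTA reading, cleaning, circular rotation and table round-trips."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnawalk.indices import FeatureVector
from dnawalk.seqio import (
    NucleotideSequence,
    clean_symbols,
    read_fasta,
    read_feature_table,
    read_rotation_table,
    rotate,
    write_fasta,
    write_feature_table,
)

sequences = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestReadFasta:
    def test_normalizes_case_and_maps_u_to_t(self, make_fasta):
        path = make_fasta([("x", "acgu")])
        [(seq, report)] = read_fasta(path)
        assert seq.symbols == "ACGT"
        assert seq.M == 4
        assert report.n_removed == 0

    def test_drops_and_counts_non_acgt(self, make_fasta):
        path = make_fasta([("x", "ACNGT")])
        [(seq, report)] = read_fasta(path)
        assert seq.symbols == "ACGT"
        assert report.n_removed == 1
        assert report.removed_symbols == (("N", 1),)
        assert report.original_length == seq.M + report.n_removed

    def test_preserves_record_order(self, make_fasta):
        path = make_fasta([("first", "ACGT"), ("second", "TTTT")])
        records = read_fasta(path)
        assert [seq.id for seq, _ in records] == ["first", "second"]

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(path)

    def test_record_with_no_valid_symbols_names_the_record(self, make_fasta):
        path = make_fasta([("ok", "ACGT"), ("badrec", "NNN-")])
        with pytest.raises(ValueError, match="badrec"):
            read_fasta(path)

    def test_write_read_round_trip(self, tmp_path, make_fasta):
        path = make_fasta([("a", "ACGTACGT"), ("b", "GGCC")])
        seqs = [seq for seq, _ in read_fasta(path)]
        out = tmp_path / "out.fasta"
        write_fasta(seqs, out)
        again = [seq for seq, _ in read_fasta(out)]
        assert [(s.id, s.symbols) for s in again] == [(s.id, s.symbols) for s in seqs]


class TestCleaning:
    @given(st.text(max_size=200))
    def test_retained_symbols_keep_their_order(self, raw):
        cleaned, _ = clean_symbols(raw)
        expected = [c for c in raw.upper().replace("U", "T") if c in "ACGT"]
        assert list(cleaned) == expected


class TestRotate:
    @pytest.mark.parametrize("breakpoint,expected", [(0, "ACGT"), (2, "GTAC"), (4, "ACGT")])
    def test_rotation_examples(self, breakpoint, expected):
        seq = NucleotideSequence(id="x", symbols="ACGT")
        assert rotate(seq, breakpoint).symbols == expected

    def test_out_of_range_breakpoint(self):
        seq = NucleotideSequence(id="x", symbols="ACGT")
        with pytest.raises(ValueError, match="out of range"):
            rotate(seq, 5)

    def test_non_circular_sequence_refuses(self):
        seq = NucleotideSequence(id="x", symbols="ACGT", circular=False)
        with pytest.raises(ValueError, match="non-circular"):
            rotate(seq, 1)

    @given(sequences, st.integers(min_value=0, max_value=400))
    def test_rotation_is_a_bijection_preserving_counts(self, symbols, k):
        seq = NucleotideSequence(id="s", symbols=symbols)
        k = k % (seq.M + 1)
        rotated = rotate(seq, k)
        assert sorted(rotated.symbols) == sorted(seq.symbols)
        assert rotate(rotated, (seq.M - k) % seq.M).symbols == seq.symbols


class TestFeatureTable:
    def _row(self, rid="Homo sapiens"):
        return FeatureVector.from_measurements(
            id=rid, xi=1.2716, H=1.9305,
            alpha_RY=0.91549, alpha_SW=0.91484, alpha_KM=0.91255,
            beta_RY=0.76264, beta_SW=0.73476, beta_KM=0.8657,
            D=0.0123, C=0.0237,
        )

    def test_single_row_gives_header_plus_row(self, tmp_path):
        out = tmp_path / "features.tsv"
        write_feature_table([self._row()], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t")[0] == "id"

    def test_round_trip_reproduces_values(self, tmp_path):
        row = self._row()
        out = tmp_path / "features.tsv"
        write_feature_table([row], out)
        df = read_feature_table(out)
        for col in ("xi", "H", "alpha_RY", "beta_KM", "v1", "v2", "v3"):
            assert math.isclose(df[col][0], getattr(row, col), abs_tol=1e-9)

    def test_empty_rows_error(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_feature_table([], tmp_path / "nope.tsv")


class TestRotationTable:
    def test_reads_id_breakpoint_pairs(self, tmp_path):
        path = tmp_path / "rot.tsv"
        path.write_text("seqA\t120\nseqB\t0\n")
        assert read_rotation_table(path) == {"seqA": 120, "seqB": 0}

    def test_duplicate_ids_error(self, tmp_path):
        path = tmp_path / "rot.tsv"
        path.write_text("seqA\t120\nseqA\t5\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_rotation_table(path)
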