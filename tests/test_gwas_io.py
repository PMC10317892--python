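"""I/O, validation, harmonisation and LD computation."""

import gzip

import numpy as np
import pytest

from targetmr.gwas_io import (DegenerateVariantError, EmptyInputError,
                              EmptyIntersectionError, FormatError,
                              GenotypeDosageMatrix, IllConditionedLDError,
                              LDMatrix, SummaryStatsTable, compute_ld,
                              harmonise_pair, read_ld_matrix,
                              read_summary_stats, write_ld_matrix,
                              write_summary_stats)

from conftest import record

HEADER = "snp\tchr\tpos\tea\tnea\teaf\tbeta\tse\tpval\tn\tn_cases\n"


def _write(tmp_path, rows, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(rows))
    return str(path)


class TestReadSummaryStats:
    def test_valid_rows_loaded_with_full_precision(self, tmp_path):
        path = _write(tmp_path, [
            "rs1\t3\t12400000\tA\tG\t0.11\t-0.074\t0.007\t1.03e-24\t1114458\t148726\n",
            "rs2\t3\t12410000\tT\tC\t0.58\t-0.028\t0.005\t9.56e-10\t1114458\t\n",
        ])
        table, report = read_summary_stats(path, "t2d", "binary")
        assert len(table) == 2 and report.n_rejected == 0
        rec = table.get("rs1")
        assert rec.beta == -0.074 and rec.n_cases == 148726
        assert table.get("rs2").n_cases is None

    @pytest.mark.parametrize("row,reason", [
        ("rsA\t1\t100\tA\tG\t0.3\t0.05\t0\t1e-5\t1000\t\n", "nonpositive SE"),
        ("rsB\t1\t100\tA\tG\t1.2\t0.05\t0.01\t1e-5\t1000\t\n",
         "EAF out of range"),
        ("rsC\t1\t100\tA\tA\t0.3\t0.05\t0.01\t1e-5\t1000\t\n",
         "identical alleles"),
        ("rsD\t1\t100\tA\tG\t0.3\t0.05\t0.01\t0.0\t1000\t\n",
         "p-value outside (0,1]"),
        ("rsE\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-5\t1000\t2000\n",
         "n_cases exceeds n"),
    ])
    def test_invalid_rows_rejected_with_reason(self, tmp_path, row, reason):
        path = _write(tmp_path, [
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-5\t1000\t\n", row])
        table, report = read_summary_stats(path, "t", "quantitative")
        assert len(table) == 1
        assert report.rejections[0][1] == reason

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\tchr\tpos\n")
        with pytest.raises(FormatError):
            read_summary_stats(str(path), "t", "binary")

    def test_all_rows_invalid_is_empty_input(self, tmp_path):
        path = _write(tmp_path, [
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0\t1e-5\t1000\t\n"])
        with pytest.raises(EmptyInputError):
            read_summary_stats(str(path), "t", "binary")

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "stats.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(HEADER +
                     "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-5\t1000\t\n")
        table, _ = read_summary_stats(str(path), "t", "quantitative")
        assert len(table) == 1

    def test_round_trip_lossless(self, tmp_path, small_table):
        path = tmp_path / "out.tsv"
        write_summary_stats(small_table, str(path))
        back, _ = read_summary_stats(str(path), "trait", "quantitative")
        for orig, new in zip(small_table.records, back.records):
            assert orig == new


class TestHarmonise:
    def test_allele_flip_negates_beta_and_mirrors_eaf(self):
        exp = SummaryStatsTable("e", "quantitative",
                                [record("rs1", ea="A", nea="G", beta=0.05)])
        out = SummaryStatsTable("o", "quantitative",
                                [record("rs1", ea="G", nea="A", beta=0.02,
                                        eaf=0.7)])
        _, out_h, dropped = harmonise_pair(exp, out)
        rec = out_h.get("rs1")
        assert rec.beta == -0.02 and rec.eaf == pytest.approx(0.3)
        assert (rec.ea, rec.nea) == ("A", "G") and not dropped

    def test_identical_coding_unchanged(self):
        exp = SummaryStatsTable("e", "quantitative", [record("rs1")])
        out = SummaryStatsTable("o", "quantitative",
                                [record("rs1", beta=0.02)])
        _, out_h, _ = harmonise_pair(exp, out)
        assert out_h.get("rs1").beta == 0.02

    def test_incompatible_alleles_dropped_and_logged(self):
        exp = SummaryStatsTable("e", "quantitative", [
            record("rs1", ea="A", nea="G"), record("rs2", ea="A", nea="G")])
        out = SummaryStatsTable("o", "quantitative", [
            record("rs1", ea="C", nea="T"), record("rs2", ea="A", nea="G")])
        exp_h, out_h, dropped = harmonise_pair(exp, out)
        assert out_h.variant_ids == ["rs2"]
        assert dropped == [("rs1", "allele mismatch")]

    def test_flip_is_involutive(self):
        from targetmr.gwas_io import _flip
        rec = record("rs1", ea="A", nea="G", beta=0.05, eaf=0.3)
        back = _flip(_flip(rec))
        assert back.beta == rec.beta
        assert back.eaf == pytest.approx(rec.eaf)
        assert (back.ea, back.nea) == (rec.ea, rec.nea)

    def test_palindromic_ambiguous_dropped_unambiguous_aligned(self):
        exp = SummaryStatsTable("e", "quantitative", [
            record("rs1", ea="A", nea="T", eaf=0.50),
            record("rs2", ea="C", nea="G", eaf=0.10)])
        out = SummaryStatsTable("o", "quantitative", [
            record("rs1", ea="A", nea="T", eaf=0.50, beta=0.02),
            record("rs2", ea="C", nea="G", eaf=0.90, beta=0.02)])
        _, out_h, dropped = harmonise_pair(exp, out)
        # rs1 near 50% cannot be resolved; rs2 frequencies disagree in
        # orientation, so the outcome record is flipped
        assert [d[0] for d in dropped] == ["rs1"]
        assert out_h.get("rs2").beta == pytest.approx(-0.02)

    def test_no_shared_variants_raises(self):
        exp = SummaryStatsTable("e", "quantitative", [record("rs1")])
        out = SummaryStatsTable("o", "quantitative", [record("rs9")])
        with pytest.raises(EmptyIntersectionError):
            harmonise_pair(exp, out)


class TestComputeLD:
    def _panel(self, cols):
        arr = np.column_stack(cols)
        return GenotypeDosageMatrix(
            [f"s{i}" for i in range(arr.shape[0])],
            [f"v{j}" for j in range(arr.shape[1])], arr)

    def test_identical_columns_give_r_one(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        ld = compute_ld(self._panel([g, g.copy()]))
        assert ld.r[0, 1] == pytest.approx(1.0)

    def test_reflected_column_gives_r_minus_one(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        ld = compute_ld(self._panel([g, 2 - g]))
        assert ld.r[0, 1] == pytest.approx(-1.0)

    def test_recovers_generating_correlation(self, rng):
        # three Gaussian columns with generating correlation 0.5, mapped to
        # dosage range; Pearson r is affine-invariant
        n = 10_000
        target = np.full((3, 3), 0.5)
        np.fill_diagonal(target, 1.0)
        z = rng.multivariate_normal(np.zeros(3), target, size=n)
        dos = 2 / (1 + np.exp(-z))  # monotone map into [0, 2]
        ld = compute_ld(self._panel(list(dos.T)))
        off = ld.r[np.triu_indices(3, 1)]
        # logistic mapping slightly attenuates r; direct Pearson on the
        # same draws is the oracle
        expected = np.corrcoef(dos, rowvar=False)[np.triu_indices(3, 1)]
        assert np.allclose(off, expected, atol=1e-12)
        assert np.all(np.abs(off - 0.5) < 0.05)

    def test_monomorphic_variant_raises(self):
        with pytest.raises(DegenerateVariantError, match="v1"):
            compute_ld(self._panel([np.array([0.0, 1, 2]),
                                    np.array([1.0, 1, 1])]))


class TestLDMatrix:
    def test_mild_negative_eigenvalue_repaired(self):
        r = np.array([[1, 0.6, 0.6], [0.6, 1, 0.6], [0.6, 0.6, 1.0]])
        # perturb into slight non-PSD
        lam, vec = np.linalg.eigh(r)
        lam[0] = -5e-7
        bad = (vec * lam) @ vec.T
        d = np.sqrt(np.diag(bad))
        bad = bad / np.outer(d, d)
        ld = LDMatrix(["a", "b", "c"], bad)
        assert np.linalg.eigvalsh(ld.r)[0] >= -1e-12

    def test_strongly_negative_eigenvalue_rejected(self):
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(IllConditionedLDError):
            LDMatrix(["a", "b", "c"], bad)

    def test_round_trip_file(self, tmp_path):
        ld = LDMatrix(["a", "b"], np.array([[1, 0.3], [0.3, 1.0]]))
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, str(path))
        back = read_ld_matrix(str(path))
        assert back.variant_ids == ld.variant_ids
        assert np.allclose(back.r, ld.r)
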