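"""Cis-instrument construction cascade and strength diagnostics."""

import itertools

import numpy as np
import pytest

from targetmr import fixtures
from targetmr.gwas_io import LDMatrix, SummaryStatsTable
from targetmr.instruments import (GeneRegion, InstrumentVariant,
                                  NoInstrumentError, build_instrument,
                                  concordance_filter, construct_instrument,
                                  instrument_strength, ld_prune,
                                  select_cis_snps)

from conftest import record


def make_variant(vid="rs1", beta_sel=-0.05, beta_sca=-0.02, eaf=0.3,
                 se_sca=0.002):
    return InstrumentVariant(vid, "A", "G", eaf, beta_sel, 0.005, 1e-10,
                             beta_sca, se_sca)


class TestSelectCis:
    REGION = GeneRegion("PPARG", "3", 12_328_867, 12_475_855)

    def test_window_bounds_are_closed(self):
        lo = self.REGION.cis_start
        hi = self.REGION.cis_end
        assert (lo, hi) == (11_828_867, 12_975_855)
        table = SummaryStatsTable("t", "binary", [
            record("rs_lo", chrom="3", pos=lo, pval=1e-10),
            record("rs_hi", chrom="3", pos=hi, pval=1e-10),
            record("rs_out", chrom="3", pos=lo - 1, pval=1e-10),
            record("rs_chr", chrom="4", pos=lo, pval=1e-10),
        ])
        kept = select_cis_snps(table, self.REGION)
        assert sorted(kept.variant_ids) == ["rs_hi", "rs_lo"]

    def test_sorted_by_p_ascending(self):
        table = SummaryStatsTable("t", "binary", [
            record("a", chrom="3", pos=12_400_000, pval=1e-9),
            record("b", chrom="3", pos=12_400_100, pval=1e-20),
        ])
        assert select_cis_snps(table, self.REGION).variant_ids == ["b", "a"]

    def test_no_significant_variant_flags_no_instrument(self):
        table = SummaryStatsTable("t", "binary", [
            record("a", chrom="3", pos=12_400_000, pval=5e-8)])
        with pytest.raises(NoInstrumentError):
            select_cis_snps(table, self.REGION)


def _greedy_oracle(pvals, r2, r2_max):
    """Lexicographically first (by p-rank) maximal admissible subset,
    found by exhaustive enumeration."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    rank = {v: i for i, v in enumerate(order)}
    admissible = []
    for size in range(m, 0, -1):
        for combo in itertools.combinations(range(m), size):
            if all(r2[i, j] < r2_max
                   for i, j in itertools.combinations(combo, 2)):
                rest = set(range(m)) - set(combo)
                maximal = all(
                    any(r2[i, j] >= r2_max for j in combo) for i in rest)
                if maximal:
                    admissible.append(tuple(sorted(combo,
                                                   key=lambda i: rank[i])))
    return min(admissible, key=lambda c: tuple(rank[i] for i in c))


class TestLDPrune:
    def _table(self, pvals):
        return SummaryStatsTable("t", "binary", [
            record(f"v{i}", pos=1000 + i, pval=p)
            for i, p in enumerate(pvals)])

    def test_worked_three_variant_example(self):
        r2 = np.array([[1, 0.5, 0.01], [0.5, 1, 0.01], [0.01, 0.01, 1.0]])
        ld = LDMatrix(["v0", "v1", "v2"], np.sqrt(r2))
        kept = ld_prune(self._table([1e-20, 1e-10, 1e-9]), ld)
        assert kept.variant_ids == ["v0", "v2"]

    def test_all_weak_ld_all_retained(self, identity_ld):
        table = self._table([1e-20, 1e-10, 1e-9])
        kept = ld_prune(table, identity_ld(["v0", "v1", "v2"]))
        assert len(kept) == 3

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(25):
            m = rng.integers(2, 9)
            a = rng.standard_normal((m + 3, m))
            r = np.corrcoef(a, rowvar=False)
            pvals = 10.0 ** (-rng.uniform(8, 30, size=m))
            ld = LDMatrix([f"v{i}" for i in range(m)], r)
            kept = ld_prune(self._table(pvals), ld, r2_max=0.2)
            oracle = _greedy_oracle(pvals, r ** 2, 0.2)
            assert kept.variant_ids == [f"v{i}" for i in oracle]

    def test_missing_variant_raises_coverage_error(self, identity_ld):
        from targetmr.instruments import CoverageError
        with pytest.raises(CoverageError):
            ld_prune(self._table([1e-9, 1e-10]), identity_ld(["v0"]))


class TestConcordance:
    def test_all_concordant_retained(self):
        variants = [make_variant(f"v{i}") for i in range(7)]
        kept, removed = concordance_filter(variants)
        assert len(kept) == 7 and not removed

    def test_discordant_removed(self):
        kept, removed = concordance_filter(
            [make_variant("bad", beta_sel=-0.05, beta_sca=0.01)])
        assert not kept and removed == [("bad", "discordant direction")]

    def test_zero_scaling_beta_removed_as_undefined(self):
        _, removed = concordance_filter([make_variant("z", beta_sca=0.0)])
        assert removed == [("z", "undefined direction")]


class TestStrength:
    def test_f_closed_form(self, identity_ld):
        # eaf=0.5, beta=1 -> explained variance 0.5; n=12, k=1 ->
        # F = (12-1-1)/1 * 0.5/0.5 = 10
        v = make_variant(beta_sca=-1.0, eaf=0.5)
        r2, f, _ = instrument_strength([v], identity_ld(["rs1"]), 12)
        assert r2 == pytest.approx(0.5)
        assert f == pytest.approx(10.0)

    def test_per_variant_f_matches_z_squared(self, identity_ld):
        v = make_variant("rs5219", beta_sca=-0.016, se_sca=0.002)
        _, _, per = instrument_strength([v], identity_ld(["rs5219"]),
                                        407_766)
        assert per["rs5219"] == pytest.approx(64.0)

    def test_additive_under_independence(self, identity_ld):
        vs = [make_variant(f"v{i}", beta_sca=-0.02, eaf=0.3)
              for i in range(4)]
        ld = identity_ld([v.variant_id for v in vs])
        r2, _, _ = instrument_strength(vs, ld, 100_000)
        single = 2 * 0.3 * 0.7 * 0.02 ** 2
        assert r2 == pytest.approx(4 * single)

    def test_ld_correction_shrinks_r2_for_correlated_variants(self):
        vs = [make_variant(f"v{i}", beta_sca=-0.02, eaf=0.3)
              for i in range(2)]
        r = np.array([[1, 0.4], [0.4, 1.0]])
        ld = LDMatrix(["v0", "v1"], r)
        r2_corr, _, _ = instrument_strength(vs, ld, 100_000)
        r2_naive, _, _ = instrument_strength(vs, ld, 100_000,
                                             ld_corrected=False)
        assert r2_corr < r2_naive

    def test_f_monotone_in_r2(self, identity_ld):
        ld = identity_ld(["v0"])
        f_vals = []
        for beta in (0.01, 0.02, 0.04):
            v = make_variant("v0", beta_sca=-beta)
            _, f, _ = instrument_strength([v], ld, 10_000)
            f_vals.append(f)
        assert f_vals == sorted(f_vals)

    def test_small_n_rejected(self, identity_ld):
        with pytest.raises(ValueError, match="F undefined"):
            instrument_strength([make_variant()], identity_ld(["rs1"]), 2)


class TestBuildInstrument:
    def test_lowering_orientation_flips_sign_convention(self, identity_ld):
        v = make_variant("rs5219", beta_sca=-0.016)
        inst = build_instrument("ABCC8", [v], identity_ld(["rs5219"]),
                                orientation="lowering", n_exposure=10_000)
        assert inst.exposure_betas[0] == pytest.approx(0.016)

    def test_raising_orientation_keeps_betas(self, identity_ld):
        v = make_variant("rs5219", beta_sca=-0.016)
        inst = build_instrument("ABCC8", [v], identity_ld(["rs5219"]),
                                orientation="raising", n_exposure=10_000)
        assert inst.exposure_betas[0] == pytest.approx(-0.016)


class TestPublishedFixtures:
    """Construction replayed on the published instrument table."""

    @pytest.mark.parametrize("gene,k", [("PPARG", 7), ("ABCC8", 6),
                                        ("GLP1R", 4)])
    def test_instrument_sizes(self, gene, k):
        sel, sca = fixtures.instrument_tables(gene)
        ld = fixtures.weak_ld_matrix(gene)
        inst = construct_instrument(gene, sel, sca,
                                    fixtures.GENE_REGIONS[gene], ld)
        assert len(inst) == k
        assert not inst.removal_log  # all printed variants are concordant
        assert inst.f_statistic > 10

    def test_all_pairwise_r2_below_threshold(self):
        sel, sca = fixtures.instrument_tables("PPARG")
        ld = fixtures.weak_ld_matrix("PPARG")
        inst = construct_instrument("PPARG", sel, sca,
                                    fixtures.GENE_REGIONS["PPARG"], ld)
        r2 = inst.ld.r ** 2
        off = r2[~np.eye(len(inst), dtype=bool)]
        assert np.all(off < 0.20)
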