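"""Instrument selection: cis window, LD clumping, R^2 and F statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pqtlscreen.instruments import (
    Ar1Ld,
    ExplicitLd,
    GeneRegion,
    SelectionThresholds,
    cis_filter,
    f_statistic,
    ld_clump,
    read_gene_regions,
    select_top_instrument,
    variance_explained,
)
from pqtlscreen.sumstats import SumstatsTable

from conftest import make_sumstats_df


def _table(rows, trait_id="G"):
    return SumstatsTable(trait_id, "quantitative", make_sumstats_df(rows))


class TestCisFilter:
    REGION = GeneRegion("G", "1", 2_000_000, 2_010_000, cis_flank=1_000_000)

    def test_boundary_position_inclusive(self):
        t = _table([("rs1", "1", 1_000_000, "A", "G", 0.2, 0.1, 0.05, 1e-9, 3000)])
        assert len(cis_filter(t, self.REGION)) == 1

    def test_just_outside_excluded(self):
        t = _table([("rs1", "1", 999_999, "A", "G", 0.2, 0.1, 0.05, 1e-9, 3000)])
        assert cis_filter(t, self.REGION).empty

    def test_other_chromosome_excluded(self):
        t = _table([("rs1", "2", 2_000_000, "A", "G", 0.2, 0.1, 0.05, 1e-9, 3000)])
        assert cis_filter(t, self.REGION).empty

    def test_cis_interval_clipped_at_one(self):
        r = GeneRegion("G", "1", 100, 200, cis_flank=1_000_000)
        assert r.cis_start == 1


class TestLdClump:
    def _records(self, spec):
        """spec: list of (variant_id, pos, pval)."""
        return make_sumstats_df(
            [(v, "1", p, "A", "G", 0.2, 0.1, 0.05, pv, 3000) for v, p, pv in spec]
        )

    def test_correlated_pair_keeps_smaller_p(self):
        recs = self._records([("a", 1000, 1e-10), ("b", 2000, 1e-9)])
        ld = ExplicitLd({("a", "b"): 0.9})
        kept = ld_clump(recs, ld, r2_max=0.8, window_kb=10_000)
        assert list(kept["variant_id"]) == ["a"]

    def test_below_threshold_pair_both_kept(self):
        recs = self._records([("a", 1000, 1e-10), ("b", 2000, 1e-9)])
        ld = ExplicitLd({("a", "b"): 0.5})
        kept = ld_clump(recs, ld, r2_max=0.8, window_kb=10_000)
        assert sorted(kept["variant_id"]) == ["a", "b"]

    def test_outside_window_not_clumped(self):
        recs = self._records([("a", 1000, 1e-10), ("b", 20_000_000, 1e-9)])
        ld = ExplicitLd({})  # lookup would fail if attempted
        kept = ld_clump(recs, ld, r2_max=0.8, window_kb=10_000)
        assert len(kept) == 2

    def test_three_mutually_correlated_single_survivor(self):
        spec = [("a", 1000, 1e-8), ("b", 2000, 1e-10), ("c", 3000, 1e-9)]
        recs = self._records(spec)
        ld = ExplicitLd({(x, y): 0.99 for x, y in itertools.combinations("abc", 2)})
        kept = ld_clump(recs, ld, r2_max=0.8, window_kb=10_000)
        assert list(kept["variant_id"]) == ["b"]
        # brute-force oracle: a subset is a legal clumping outcome iff it is
        # pairwise independent and every removed variant was removable, i.e.
        # correlated (within window) with a kept variant of better (p, pos)
        # rank; for this triple the only such subset is {b}
        order = {v: (p, pos) for v, pos, p in spec}
        legal = []
        for r in range(1, 4):
            for s in itertools.combinations("abc", r):
                indep = all(ld.r2(x, y) < 0.8 for x, y in itertools.combinations(s, 2))
                removable = all(
                    any(ld.r2(x, y) >= 0.8 and order[y] < order[x] for y in s)
                    for x in "abc" if x not in s
                )
                if indep and removable:
                    legal.append(set(s))
        assert legal == [{"b"}]

    def test_missing_ld_for_in_window_pair_raises(self):
        recs = self._records([("a", 1000, 1e-10), ("b", 2000, 1e-9)])
        with pytest.raises(LookupError):
            ld_clump(recs, ExplicitLd({}), r2_max=0.8, window_kb=10_000)

    def test_equal_pvalues_tie_broken_by_position(self):
        recs = self._records([("late", 5000, 1e-9), ("early", 1000, 1e-9)])
        ld = ExplicitLd({("late", "early"): 0.99})
        kept = ld_clump(recs, ld, r2_max=0.8, window_kb=10_000)
        assert list(kept["variant_id"]) == ["early"]

    def test_output_pairwise_independent_random_inputs(self, rng):
        """No retained pair within the window has r^2 >= threshold."""
        for _ in range(20):
            m = int(rng.integers(2, 12))
            pos = np.sort(rng.integers(1, 5_000_000, size=m))
            ids = [f"v{i}" for i in range(m)]
            recs = self._records(
                [(ids[i], int(pos[i]), float(rng.uniform(1e-12, 1e-3))) for i in range(m)]
            )
            r2_map = {
                (ids[i], ids[j]): float(rng.uniform(0, 1))
                for i in range(m) for j in range(i + 1, m)
            }
            ld = ExplicitLd(r2_map)
            kept = ld_clump(recs, ld, r2_max=0.8, window_kb=1000)
            for a, b in itertools.combinations(kept.itertuples(index=False), 2):
                if abs(a.pos - b.pos) <= 1_000_000:
                    assert ld.r2(a.variant_id, b.variant_id) < 0.8


class TestStrengthStatistics:
    def test_variance_explained_algebraic_identity(self):
        # beta equal to one trait SD at eaf 0.5: r2 = 2 * 0.25 = 0.5
        assert variance_explained(0.5, 0.02 * np.sqrt(100), 0.02, 100) == pytest.approx(0.5)

    def test_variance_explained_direct_arithmetic(self):
        assert variance_explained(0.25, 0.1, 0.01, 100) == pytest.approx(0.375)

    def test_maf_folding_symmetry(self):
        assert variance_explained(0.75, 0.1, 0.01, 100) == pytest.approx(
            variance_explained(0.25, 0.1, 0.01, 100)
        )

    def test_variance_explained_clipped_below_one(self):
        with pytest.warns(UserWarning, match="clipped"):
            r2 = variance_explained(0.5, 100.0, 0.01, 10)
        assert r2 < 1.0

    def test_f_statistic_values(self):
        assert f_statistic(0.5, 102, 1) == pytest.approx(100.0)
        assert f_statistic(0.01, 1002, 1) == pytest.approx(0.01 * 1000 / 0.99)
        assert f_statistic(0.0, 100, 1) == 0.0

    def test_f_monotone_in_r2_and_n(self):
        r2s = np.linspace(0.0, 0.9, 25)
        fs = [f_statistic(r, 1000, 1) for r in r2s]
        assert np.all(np.diff(fs) > 0)
        ns = np.arange(100, 2000, 100)
        fs = [f_statistic(0.1, n, 1) for n in ns]
        assert np.all(np.diff(fs) > 0)


class TestSelectTopInstrument:
    REGION = GeneRegion("G", "1", 1_040_000, 1_060_000, cis_flank=1_000_000)

    def test_single_genomewide_variant_selected(self):
        t = _table([("rs1", "1", 1_050_000, "A", "G", 0.2, 0.5, 0.02, 1e-9, 3000)])
        inst = select_top_instrument(t, self.REGION)
        assert inst is not None
        assert inst.variant_id == "rs1"
        assert inst.k == 1
        assert not inst.relaxed
        assert inst.f_stat > 10 and not inst.weak

    def test_nothing_below_fallback_threshold_returns_none(self):
        t = _table([("rs1", "1", 1_050_000, "A", "G", 0.2, 0.1, 0.05, 2e-5, 3000)])
        assert select_top_instrument(t, self.REGION) is None

    def test_relaxed_fallback_cascade(self):
        """Primary 5e-8 tier empty -> retry at 1e-5 and flag relaxed.

        Hand enumeration of the cascade over this 5-variant fixture:
        rs_maf fails MAF; rs_far is outside the cis window; rs_weak fails
        both p thresholds; rs_a (1e-7) and rs_b (1e-6) fail the primary
        threshold but pass the fallback; smallest p wins.
        """
        t = _table([
            ("rs_a", "1", 1_050_000, "A", "G", 0.2, 0.3, 0.055, 1e-7, 3000),
            ("rs_b", "1", 1_051_000, "C", "T", 0.3, 0.25, 0.05, 1e-6, 3000),
            ("rs_maf", "1", 1_052_000, "A", "C", 0.005, 0.9, 0.1, 1e-9, 3000),
            ("rs_weak", "1", 1_053_000, "G", "A", 0.4, 0.05, 0.05, 0.3, 3000),
            ("rs_far", "1", 9_000_000, "T", "C", 0.2, 0.8, 0.05, 1e-12, 3000),
        ])
        ld = ExplicitLd({(a, b): 0.1 for a, b in itertools.combinations(
            ["rs_a", "rs_b", "rs_maf", "rs_weak", "rs_far"], 2)})
        inst = select_top_instrument(t, self.REGION, ld=ld)
        assert inst is not None
        assert inst.variant_id == "rs_a"
        assert inst.relaxed

    def test_selected_variant_passes_every_filter(self, rng):
        thresholds = SelectionThresholds()
        for _ in range(10):
            m = int(rng.integers(1, 15))
            rows = []
            for i in range(m):
                rows.append((
                    f"v{i}", "1", int(rng.integers(500_000, 2_500_000)), "A", "G",
                    float(rng.uniform(0.003, 0.5)), float(rng.normal(0, 0.3)),
                    float(rng.uniform(0.01, 0.1)),
                    float(10 ** rng.uniform(-12, -0.01)), 3000,
                ))
            t = _table(rows)
            ld = ExplicitLd({(f"v{i}", f"v{j}"): float(rng.uniform(0, 1))
                             for i in range(m) for j in range(i + 1, m)})
            inst = select_top_instrument(t, self.REGION, thresholds, ld)
            if inst is None:
                continue
            row = t.df.set_index("variant_id").loc[inst.variant_id]
            assert self.REGION.cis_start <= row["pos"] <= self.REGION.cis_end
            assert min(row["eaf"], 1 - row["eaf"]) > thresholds.maf_min
            assert row["pval"] < thresholds.single_iv_pval_max


class TestLdProviders:
    def test_ar1_r2_is_squared_correlation(self):
        ld = Ar1Ld(["a", "b", "c"], rho=0.9)
        assert ld.r2("a", "b") == pytest.approx(0.81)
        assert ld.r2("a", "c") == pytest.approx(0.9**4)
        assert ld.r2("b", "b") == 1.0


def test_read_gene_regions_bed_conversion(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("1\t1999999\t2010000\tG1\n")
    (region,) = read_gene_regions(p, bed=True)
    assert (region.start, region.end) == (2_000_000, 2_010_000)  # 0-based half-open -> 1-based

    q = tmp_path / "regions.tsv"
    q.write_text("gene_id\tchrom\tstart\tend\nG1\t1\t2000000\t2010000\n")
    (region2,) = read_gene_regions(q)
    assert (region2.start, region2.end) == (2_000_000, 2_010_000)
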