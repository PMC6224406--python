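"""CNV event calling, chromosome amplification, karyotype, enrichment."""

import numpy as np
import pandas as pd
import pytest

from regdriver.cnv import (
    assign_karyotype,
    call_events,
    chromosome_amplified,
    cnv_translocation_enrichment,
    cre_cnv_expression,
    genes_near_breakpoints,
)
from regdriver.expression import ExpressionMatrix
from regdriver.regions import GenomicInterval


def _seg(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "log2_ratio"])


class TestCallEvents:
    def test_boundary_log2_and_focal_size(self):
        ev = call_events(_seg([("S1", "chr1", 0, 2_900_000, 0.1613)]),
                         focal_only=True)
        assert len(ev) == 1 and ev.iloc[0]["direction"] == "amplification"

    def test_large_event_not_focal(self):
        seg = _seg([("S1", "chr1", 0, 3_100_000, -0.2)])
        assert len(call_events(seg)) == 1
        assert len(call_events(seg, focal_only=True)) == 0

    def test_below_threshold_no_event(self):
        assert len(call_events(_seg([("S1", "chr1", 0, 1000, 0.1)]))) == 0


class TestChromosomeAmplified:
    lengths = {"chr1": 1_000_000}

    def test_single_large_amplification(self):
        out = chromosome_amplified(_seg([("S", "chr1", 0, 950_000, 0.3)]),
                                   self.lengths)
        assert out["chr1"] is True

    def test_disjoint_amplifications_union(self):
        seg = _seg([("S", "chr1", 0, 500_000, 0.3),
                    ("S", "chr1", 550_000, 960_000, 0.4)])
        assert chromosome_amplified(seg, self.lengths)["chr1"] is True  # 91%

    def test_just_below_ninety_percent(self):
        seg = _seg([("S", "chr1", 0, 899_000, 0.3)])
        assert chromosome_amplified(seg, self.lengths)["chr1"] is False

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError):
            chromosome_amplified(_seg([("S", "chrX", 0, 100, 0.3)]), {})

    def test_union_matches_bitmap_oracle(self):
        rng = np.random.default_rng(0)
        L = 100_000
        for trial in range(20):
            n = rng.integers(1, 8)
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                rows.append(("S", "chr1", s, e, 0.3))
            seg = _seg(rows)
            got = chromosome_amplified(seg, {"chr1": L})["chr1"]
            bitmap = np.zeros(L, dtype=bool)
            for _, _, s, e, _ in seg.itertuples(index=False):
                bitmap[s:e] = True
            assert got == (bitmap.mean() >= 0.90)


class TestAssignKaryotype:
    lengths = {f"chr{i}": 1_000_000 for i in list(range(1, 23)) + ["X"]}

    def test_two_amplified_autosomes_is_hd(self):
        seg = _seg([("S", "chr3", 0, 950_000, 0.3),
                    ("S", "chr5", 0, 950_000, 0.3)])
        assert assign_karyotype("S", seg, self.lengths).hd is True

    def test_sex_chromosome_does_not_count(self):
        seg = _seg([("S", "chr3", 0, 950_000, 0.3),
                    ("S", "chrX", 0, 950_000, 0.3)])
        call = assign_karyotype("S", seg, self.lengths)
        assert call.hd is False
        assert "chrX" in call.amplified_chromosomes

    def test_no_amplification_not_hd(self):
        assert assign_karyotype("S", _seg([]), self.lengths).hd is False


class TestTranslocationEnrichment:
    def test_tiny_table_enumeration(self):
        # group = {a, b} translocated; others not: (2,0;0,2) -> p = 1/6
        cohort = {"a", "b", "c", "d"}
        table, odds, p = cnv_translocation_enrichment(
            {"a", "b"}, {"a", "b"}, cohort)
        assert p == pytest.approx(1 / 6)

    def test_null_direction_large_p(self):
        cohort = {f"s{i}" for i in range(100)}
        trans = {f"s{i}" for i in range(0, 100, 4)}        # 25%
        group = ({f"s{i}" for i in range(0, 20, 4)}
                 | {f"s{i}" for i in range(1, 30, 2)})  # 5/20 translocated
        _, _, p = cnv_translocation_enrichment(group, trans, cohort)
        assert p > 0.05

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cnv_translocation_enrichment(set(), set(), set())

    def test_invariant_under_simultaneous_row_col_swap(self):
        from regdriver.stats import fisher_exact
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b, c, d = rng.integers(0, 30, 4)
            _, p1 = fisher_exact([[a, b], [c, d]], "greater")
            _, p2 = fisher_exact([[d, c], [b, a]], "greater")
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestGenesNearBreakpoints:
    genes = pd.DataFrame(
        [("gA", "chr1", 2_000_000, 2_010_000),
         ("gB", "chr1", 4_000_001, 4_010_000),
         ("gC", "chr2", 0, 10_000)],
        columns=["gene", "chrom", "start", "end"])

    def test_boundary_inclusive(self):
        # gA start is exactly 1 Mb from breakpoint
        assert genes_near_breakpoints([("chr1", 1_000_000)], self.genes) == ["gA"]

    def test_beyond_window_excluded(self):
        # gB starts 1,000,001 bp past the breakpoint: just outside
        assert genes_near_breakpoints([("chr1", 3_000_000)], self.genes) == ["gA"]
        assert genes_near_breakpoints([("chr1", 5_010_001)], self.genes) == []

    def test_flanking_breakpoints_deduplicate(self):
        out = genes_near_breakpoints(
            [("chr1", 1_900_000), ("chr1", 2_100_000)], self.genes)
        assert out == ["gA"]


class TestCreCnvExpression:
    cre = GenomicInterval("chr1", 100_000, 102_000)
    gene = GenomicInterval("chr1", 500_000, 510_000)

    @staticmethod
    def _expr(samples, mu_map, seed=0):
        # 50 stable background genes so library sizes are well defined
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            {s: np.concatenate([[rng.poisson(mu_map.get(s, 100))],
                                rng.poisson(100, 50)]) for s in samples},
            index=["G"] + [f"bg{i}" for i in range(50)])
        return ExpressionMatrix(counts)

    def test_group_below_seven_skipped(self):
        samples = [f"s{i}" for i in range(30)]
        seg = _seg([(f"s{i}", "chr1", 99_000, 103_000, 0.4) for i in range(6)])
        expr = self._expr(samples, {})
        out = cre_cnv_expression(self.cre, "G", self.gene, seg, expr)
        assert out == []

    def test_no_cnv_at_cre_no_test(self):
        samples = [f"s{i}" for i in range(20)]
        out = cre_cnv_expression(self.cre, "G", self.gene, _seg([]),
                                 self._expr(samples, {}))
        assert out == []

    def test_gene_spanning_cnv_excluded(self):
        samples = [f"s{i}" for i in range(30)]
        # 8 samples amplified at CRE only; 2 with CNV spanning CRE and gene
        rows = [(f"s{i}", "chr1", 99_000, 103_000, 0.4) for i in range(8)]
        rows += [(f"s{i}", "chr1", 90_000, 600_000, 0.4) for i in (20, 21)]
        out = cre_cnv_expression(self.cre, "G", self.gene, _seg(rows),
                                 self._expr(samples, {}), dispersion=0.0)
        assert len(out) == 1
        assert out[0]["n_group"] == 8

    def test_amplified_expression_effect_detected(self):
        samples = [f"s{i}" for i in range(60)]
        amped = {f"s{i}" for i in range(10)}
        seg = _seg([(s, "chr1", 99_000, 103_000, 0.4) for s in amped])
        expr = self._expr(samples, {s: 230 for s in amped}, seed=3)
        out = cre_cnv_expression(self.cre, "G", self.gene, seg, expr,
                                 dispersion=0.0)
        (res,) = out
        assert res["direction"] == "amplification"
        assert res["fold_change"] > 1.2 and res["p"] < 0.01
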