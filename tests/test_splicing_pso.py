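"""Splicing units, junction support, exonic coverage, PSO and its ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scc2xpress.genomic_core import GenomicInterval, TranscriptModel
from scc2xpress.splicing_pso import (
    SplicingUnit,
    compute_pso_table,
    exonic_unit_coverage,
    junction_support,
    pso,
    pso_anova,
    units_from_annotation,
)

from conftest import make_read


@pytest.fixture
def unit():
    # exons [100,200) and [300,400), intron gap [200,300)
    return SplicingUnit(
        "u1",
        GenomicInterval("chr1", 100, 200, "+"),
        GenomicInterval("chr1", 300, 400, "+"),
    )


class TestUnitsFromAnnotation:
    def test_intron_counting(self):
        e = lambda s, t: GenomicInterval("chr1", s, t, "+")
        txs = {
            "two_exon": TranscriptModel("two_exon", (e(0, 50), e(100, 150))),
            "three_exon": TranscriptModel("three_exon", (e(200, 250), e(300, 350), e(400, 450))),
            "intronless": TranscriptModel("intronless", (e(500, 600),)),
        }
        units = units_from_annotation(txs)
        by_tx = {}
        for u in units:
            by_tx.setdefault(u.unit_id.split(".")[0], []).append(u)
        assert len(by_tx["two_exon"]) == 1
        assert len(by_tx["three_exon"]) == 2
        assert "intronless" not in by_tx

    def test_minus_strand_donor_is_rightmost(self):
        e1 = GenomicInterval("chr1", 0, 50, "-")
        e2 = GenomicInterval("chr1", 100, 150, "-")
        units = units_from_annotation({"tx": TranscriptModel("tx", (e1, e2))})
        # transcription runs right-to-left: donor exon has the larger coordinates
        assert units[0].donor_exon.start == 100
        assert units[0].junction == (50, 100)

    def test_overlapping_exons_rejected(self):
        e1 = GenomicInterval("chr1", 0, 60, "+")
        e2 = GenomicInterval("chr1", 50, 100, "+")
        with pytest.raises(ValueError, match="overlap"):
            units_from_annotation({"tx": TranscriptModel("tx", (e1, e2))})


class TestJunctionSupport:
    def test_exact_gap_counts(self, unit):
        read = make_read("chr1", 150, 350, blocks=[(150, 200), (300, 350)])
        assert junction_support([read], unit) == 1

    def test_gap_off_by_one_rejected(self, unit):
        read = make_read("chr1", 150, 350, blocks=[(150, 199), (300, 350)])
        assert junction_support([read], unit) == 0
        assert junction_support([read], unit, tolerance=1) == 1

    def test_toy_mixture_matches_enumeration(self, unit):
        matching = [
            make_read("chr1", 180, 320, blocks=[(180, 200), (300, 320)]),
            make_read("chr1", 150, 390, blocks=[(150, 200), (300, 390)]),
            make_read("chr1", 199, 301, blocks=[(199, 200), (300, 301)]),
        ]
        near_miss = [
            make_read("chr1", 180, 320, blocks=[(180, 201), (301, 320)]),
            make_read("chr1", 180, 320, blocks=[(180, 200), (299, 320)]),
        ]
        unspliced = [make_read("chr1", s, s + 50) for s in (120, 220, 320)]
        reads = matching + near_miss + unspliced
        assert junction_support(reads, unit) == 3
        # independent brute-force oracle over blocks
        brute = sum(
            any(
                left.end == 200 and right.start == 300
                for left, right in zip(r.blocks, r.blocks[1:])
            )
            for r in reads
        )
        assert brute == 3


class TestExonicCoverage:
    def test_single_read_arithmetic(self, unit):
        # 100 bp fully inside the 200 bp exon pair -> 100/200
        read = make_read("chr1", 100, 200)
        assert exonic_unit_coverage([read], unit) == pytest.approx(0.5)

    def test_no_reads_zero(self, unit):
        assert exonic_unit_coverage([], unit) == 0.0

    def test_matches_per_base_brute_force(self, unit, rng):
        reads = []
        for _ in range(12):
            s = int(rng.integers(50, 420))
            reads.append(make_read("chr1", s, s + 40))
        got = exonic_unit_coverage(reads, unit)
        exon_bases = list(range(100, 200)) + list(range(300, 400))
        brute = sum(
            sum(1 for r in reads for b in r.blocks if b.start <= pos < b.end)
            for pos in exon_bases
        ) / len(exon_bases)
        assert got == pytest.approx(brute)


class TestPso:
    @pytest.mark.parametrize("jc,ec,want", [(10, 20, 50.0), (0, 20, 0.0), (20, 20, 100.0)])
    def test_arithmetic(self, jc, ec, want):
        assert pso(jc, ec) == pytest.approx(want)

    def test_zero_denominator_is_missing_not_zero(self):
        assert np.isnan(pso(0, 0))
        assert np.isnan(pso(5, 0))

    def test_invariant_under_read_duplication(self, unit):
        reads = [
            make_read("chr1", 180, 320, blocks=[(180, 200), (300, 320)]),
            make_read("chr1", 120, 170),
            make_read("chr1", 310, 360),
        ]
        one = pso(junction_support(reads, unit), exonic_unit_coverage(reads, unit))
        two = pso(junction_support(reads * 3, unit), exonic_unit_coverage(reads * 3, unit))
        assert one == pytest.approx(two)


class TestPsoAnova:
    GENOTYPES = {"wt1": "WT", "wt2": "WT", "wt3": "WT", "m1": "MUT", "m2": "MUT", "m3": "MUT"}

    def test_textbook_one_way_anova(self):
        table = pd.DataFrame(
            {"wt1": [10.0], "wt2": [12.0], "wt3": [14.0], "m1": [20.0], "m2": [22.0], "m3": [24.0]},
            index=["u1"],
        )
        out = pso_anova(table, self.GENOTYPES)
        # textbook oracle: SSB = 3*(12-17)^2 + 3*(22-17)^2 = 150, MSW = 16/4 = 4
        assert out.loc["u1", "f_stat"] == pytest.approx(150.0 / 4.0)
        assert out.loc["u1", "p"] == pytest.approx(
            stats.f.sf(37.5, 1, 4)
        )

    def test_no_between_group_variance(self):
        table = pd.DataFrame(
            {"wt1": [10.0], "wt2": [14.0], "wt3": [12.0], "m1": [10.0], "m2": [14.0], "m3": [12.0]},
            index=["u1"],
        )
        out = pso_anova(table, self.GENOTYPES)
        assert out.loc["u1", "f_stat"] == 0.0
        assert out.loc["u1", "p"] == 1.0

    def test_missing_pso_units_dropped(self):
        table = pd.DataFrame(
            {
                "wt1": [10.0, np.nan], "wt2": [12.0, 1.0], "wt3": [14.0, 1.0],
                "m1": [20.0, 1.0], "m2": [22.0, 1.0], "m3": [24.0, 1.0],
            },
            index=["u1", "u2"],
        )
        out = pso_anova(table, self.GENOTYPES)
        assert list(out.index) == ["u1"]

    def test_fewer_than_two_genotypes_rejected(self):
        table = pd.DataFrame({"wt1": [1.0], "wt2": [2.0]}, index=["u1"])
        with pytest.raises(ValueError):
            pso_anova(table, {"wt1": "WT", "wt2": "WT"})

    def test_bh_applied_across_units(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.normal(50, 5, size=(5, 6)),
            index=[f"u{i}" for i in range(5)],
            columns=list(self.GENOTYPES),
        )
        out = pso_anova(table, self.GENOTYPES)
        from scc2xpress.expression_stats import bh_adjust

        assert out["adj_p"].to_numpy() == pytest.approx(bh_adjust(out["p"].to_numpy()))
        assert np.all(out["adj_p"] >= out["p"])

    def test_null_p_values_uniform(self):
        # 200 null units, same distribution in both genotypes
        rng = np.random.default_rng(42)
        table = pd.DataFrame(
            rng.normal(60, 8, size=(200, 6)),
            index=[f"u{i}" for i in range(200)],
            columns=list(self.GENOTYPES),
        )
        out = pso_anova(table, self.GENOTYPES)
        ks_p = stats.kstest(out["p"], "uniform").pvalue
        assert ks_p > 0.01


class TestComputePsoTable:
    def test_per_sample_columns_and_low_confidence_flag(self, unit):
        deep = [make_read("chr1", 100, 400, blocks=[(100, 200), (300, 400)], sample="a")] * 3
        shallow = [make_read("chr1", 150, 160, sample="b")]
        table = compute_pso_table({"a": deep, "b": shallow}, [unit])
        assert table.loc["u1", "a"] == pytest.approx(100.0 * 3 / 3.0)
        assert bool(table.loc["u1", "low_confidence"])
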