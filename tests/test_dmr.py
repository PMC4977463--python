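"""Unit and property tests for the sliding-window DMR caller."""

import numpy as np
import pandas as pd
import pytest

from methdog.dmr import (
    DMRConfig,
    annotate_dmrs,
    call_dmrs,
    compare_sites,
    dmrs_to_frame,
    extend_run,
    implant_sensitivity,
    is_seed,
    recurrent_genes,
    region_levels,
    trim_run,
)
from methdog.io import GenomeAnnotation, join_tracks
from methdog.simulate import place_dmr_specs, simulate_genome, simulate_pair

from conftest import paired_from_counts

CFG = DMRConfig()

# count vocabulary: (donor_meth, donor_unmeth, clone_meth, clone_unmeth)
SIG = (5, 0, 0, 5)          # clone hypomethylated, p = 2/252 <= 0.01
SIG_OPP = (0, 5, 5, 0)      # clone hypermethylated, significant
NS_SAME = (4, 0, 2, 2)      # same tendency as SIG, p ~ 0.43
NS_OPP = (2, 2, 4, 0)       # opposite tendency, p ~ 0.43
NEUTRAL = (4, 4, 4, 4)      # zero difference, p = 1


def sites_at(spaced_counts, start=0, spacing=50):
    rows = [(start + i * spacing, *cnt) for i, cnt in enumerate(spaced_counts)]
    return compare_sites(paired_from_counts(rows), CFG)


class TestCompareSites:
    def test_extreme_difference(self):
        (s,) = sites_at([(8, 0, 0, 8)])
        assert s.diff == -1.0
        assert s.tendency == -1
        assert s.p == pytest.approx(2 / 12870, rel=1e-9)

    def test_identical_counts_neutral(self):
        (s,) = sites_at([NEUTRAL])
        assert (s.diff, s.tendency, s.p) == (0.0, 0, pytest.approx(1.0))

    def test_small_difference_not_significant(self):
        (s,) = sites_at([(4, 0, 3, 1)])
        assert s.diff == -0.25
        assert s.p == pytest.approx(1.0)  # enumeration gives p = 1

    def test_order_preserved(self):
        sites = sites_at([SIG, NEUTRAL, NS_OPP])
        assert [s.pos for s in sites] == [0, 50, 100]


class TestSeed:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (SIG, True),                  # p<=0.01 and |diff|=1
            ((4, 0, 3, 1), False),        # effect present, not significant
            ((100, 100, 66, 134), False), # significant but |diff|=0.17 < 0.2
        ],
    )
    def test_seed_criteria(self, counts, expected):
        (s,) = sites_at([counts])
        assert is_seed(s, CFG) is expected

    def test_stricter_p_never_adds_seeds(self):
        rng = np.random.default_rng(3)
        rows = [
            (i * 60, *rng.integers(0, 12, size=4) + [1, 1, 1, 1])
            for i in range(200)
        ]
        sites = compare_sites(paired_from_counts([tuple(map(int, r)) for r in rows]), CFG)
        loose = {s.pos for s in sites if is_seed(s, DMRConfig(p_site=0.05))}
        strict = {s.pos for s in sites if is_seed(s, DMRConfig(p_site=0.01))}
        assert strict <= loose


class TestExtendTrim:
    def test_pure_significant_run(self):
        sites = sites_at([SIG] * 5)
        assert extend_run(sites, 0, CFG) == range(0, 5)

    def test_single_opposite_tolerated(self):
        sites = sites_at([SIG, NS_OPP, SIG])
        assert extend_run(sites, 0, CFG) == range(0, 3)

    def test_two_consecutive_opposites_terminate(self):
        sites = sites_at([SIG, NS_OPP, NS_OPP, SIG])
        assert extend_run(sites, 0, CFG) == range(0, 2)  # stops after first

    def test_significant_opposite_terminates(self):
        sites = sites_at([SIG, SIG_OPP, SIG])
        assert extend_run(sites, 0, CFG) == range(0, 1)

    def test_gap_rule(self):
        sites = sites_at([SIG, SIG], spacing=201)
        assert extend_run(sites, 0, CFG) == range(0, 1)

    def test_neutral_site_not_opposite(self):
        sites = sites_at([SIG, NS_OPP, NEUTRAL, SIG])
        # neutral breaks the consecutive-opposite pair; all accepted
        assert extend_run(sites, 0, CFG) == range(0, 4)

    def test_trim_trailing_nonsignificant(self):
        sites = sites_at([SIG, SIG, NS_SAME, NS_SAME])
        run = extend_run(sites, 0, CFG)
        assert run == range(0, 4)
        assert trim_run(sites, run, CFG) == range(0, 2)

    def test_trim_keeps_significant_end(self):
        sites = sites_at([SIG, NS_SAME, SIG])
        assert trim_run(sites, range(0, 3), CFG) == range(0, 3)

    def test_trim_never_removes_seed(self):
        sites = sites_at([SIG, NS_SAME])
        assert trim_run(sites, range(0, 2), CFG) == range(0, 1)
        assert trim_run(sites, range(0, 1), CFG) == range(0, 1)


class TestRegionLevels:
    def test_pooled_arithmetic(self):
        sites = sites_at([(4, 0, 0, 4), (2, 2, 1, 3)])
        donor, clone, diff = region_levels(sites)
        assert donor == 6 / 8
        assert clone == 1 / 8
        assert diff == -0.625

    def test_single_site_equals_site_levels(self):
        sites = sites_at([SIG])
        donor, clone, diff = region_levels(sites)
        assert (donor, clone) == (sites[0].donor_level, sites[0].clone_level)

    def test_identical_samples_zero_diff(self):
        sites = sites_at([NEUTRAL, NEUTRAL])
        assert region_levels(sites)[2] == 0.0


class TestCallDmrs:
    def test_strong_run_single_dmr(self):
        sites = sites_at([(8, 0, 0, 8)] * 10, spacing=50)
        dmrs, _ = call_dmrs(sites)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.n_cpg, d.length, d.region_diff, d.direction) == (10, 451, -1.0, "hypo")

    def test_four_sites_fail_min_sites(self):
        dmrs, _ = call_dmrs(sites_at([(8, 0, 0, 8)] * 4, spacing=50))
        assert dmrs == []

    def test_identical_tracks_no_dmrs(self):
        dmrs, table = call_dmrs(sites_at([NEUTRAL] * 20, spacing=50))
        assert dmrs == []
        assert (table["p"] > 0.9).all()

    def test_sites_table_has_bh_column(self):
        _, table = call_dmrs(sites_at([SIG, NEUTRAL, NS_OPP]))
        assert "p_bh" in table.columns
        assert (table["p_bh"] >= table["p"] - 1e-12).all()

    def test_scan_resumes_after_emitted_dmr(self):
        # two strong runs separated by a 300-bp gap -> two separate DMRs
        rows = [(i * 50, 8, 0, 0, 8) for i in range(6)]
        rows += [(600 + i * 50, 0, 8, 8, 0) for i in range(6)]
        dmrs, _ = call_dmrs(compare_sites(paired_from_counts(rows), CFG))
        assert len(dmrs) == 2
        assert [d.direction for d in dmrs] == ["hypo", "hyper"]
        assert dmrs[0].end <= dmrs[1].start

    def test_chromosomes_scanned_independently(self):
        rows_a = [("chr1", i * 50, 8, 0, 0, 8) for i in range(5)]
        rows_b = [("chr2", i * 50, 8, 0, 0, 8) for i in range(5)]
        df = pd.DataFrame(
            rows_a + rows_b,
            columns=["chrom", "pos", "donor_meth", "donor_unmeth", "clone_meth", "clone_unmeth"],
        )
        from methdog.io import PairedTrack

        dmrs, _ = call_dmrs(PairedTrack("d", "c", 4, df))
        assert [d.chrom for d in dmrs] == ["chr1", "chr2"]

    def test_emitted_dmrs_satisfy_all_filters(self, small_genome):
        specs = place_dmr_specs(small_genome, 10, n_cpg=8, delta=-0.5, seed=2)
        donor, clone, _ = simulate_pair(small_genome, depth_lambda=30, dmr_specs=specs, seed=2)
        dmrs, _ = call_dmrs(join_tracks(donor, clone, CFG.min_depth))
        assert dmrs
        prev_end = {}
        for d in dmrs:
            assert d.n_cpg >= CFG.min_sites
            assert CFG.min_len <= d.length <= CFG.max_len
            assert abs(d.region_diff) >= CFG.min_region_diff
            first, last = d.sites[0], d.sites[-1]
            assert first.p <= CFG.p_site and last.p <= CFG.p_site
            sign = 1 if d.direction == "hyper" else -1
            assert first.tendency == last.tendency == sign
            gaps = np.diff([s.pos for s in d.sites])
            assert (gaps <= CFG.max_gap).all()
            assert d.start >= prev_end.get(d.chrom, -1)  # non-overlapping
            prev_end[d.chrom] = d.end


class TestAnnotation:
    ANN = GenomeAnnotation(
        pd.DataFrame(
            [("gplus", "chr1", "+", 2900, 4000), ("gminus", "chr1", "-", 5000, 8000)],
            columns=["gene_id", "chrom", "strand", "start", "end"],
        )
    )

    def make_dmr(self, start, end):
        sites = sites_at([SIG, SIG, SIG, SIG, SIG], start=start, spacing=(end - 1 - start) // 4)
        dmrs, _ = call_dmrs(sites)
        return dmrs

    def test_plus_strand_promoter_hit(self):
        (d,) = annotate_dmrs(self.make_dmr(1000, 1400), self.ANN)
        assert d.promoter_genes == ["gplus"]  # promoter [900, 2900)
        assert d.genes == []

    def test_minus_strand_promoter_hit(self):
        (d,) = annotate_dmrs(self.make_dmr(8100, 8400), self.ANN)
        assert d.promoter_genes == ["gminus"]  # promoter [8000, 10000)

    def test_intergenic_dmr_unlabelled(self):
        (d,) = annotate_dmrs(self.make_dmr(20_000, 20_400), self.ANN)
        assert d.genes == [] and d.promoter_genes == []

    def test_gene_body_overlap(self):
        (d,) = annotate_dmrs(self.make_dmr(6000, 6400), self.ANN)
        assert d.genes == ["gminus"]


class TestRecurrence:
    def test_pair_counts(self):
        table = recurrent_genes([{"A", "B"}, {"B", "C"}, {"B"}])
        counts = dict(zip(table["gene"], table["n_pairs"]))
        assert counts == {"A": 1, "B": 3, "C": 1}
        assert set(table[table["recurrent"]]["gene"]) == {"B"}

    def test_disjoint_sets_nothing_recurrent(self):
        table = recurrent_genes([{"A"}, {"B"}, {"C"}])
        assert not table["recurrent"].any()

    def test_identical_sets_all_recurrent(self):
        table = recurrent_genes([{"A", "B"}] * 3)
        assert table["recurrent"].all()
        assert (table["n_pairs"] == 3).all()


def test_dmrs_to_frame_schema():
    dmrs, _ = call_dmrs(sites_at([(8, 0, 0, 8)] * 10, spacing=50))
    frame = dmrs_to_frame(dmrs)
    assert frame.iloc[0]["start"] == 0
    assert frame.iloc[0]["end"] == 451
    assert frame.iloc[0]["direction"] == "hypo"


def test_implant_sensitivity_metric():
    truth = pd.DataFrame(
        [("chr1", 0, 451, -1.0), ("chr1", 10_000, 10_451, -1.0)],
        columns=["chrom", "start", "end", "delta"],
    )
    dmrs, _ = call_dmrs(sites_at([(8, 0, 0, 8)] * 10, spacing=50))
    assert implant_sensitivity(truth, dmrs) == 0.5
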