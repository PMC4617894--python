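import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from contextcore import fixtures
from contextcore.regulatory import (GenomicInterval, assign_nearest_gene,
                                    expression_shift, extend_to_length,
                                    load_pipeline, read_bed, regulatory_load,
                                    reproducible_regions, select_hrl,
                                    write_bed)

from ._oracles import overlap_bruteforce


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iv("chr1", 100, 100)

    def test_empty_chrom_rejected(self):
        with pytest.raises(ValueError):
            iv("", 0, 10)

    def test_overlap_semantics(self):
        assert iv("chr1", 0, 10).overlaps(iv("chr1", 9, 20))
        assert not iv("chr1", 0, 10).overlaps(iv("chr1", 10, 20))
        assert not iv("chr1", 0, 10).overlaps(iv("chr2", 0, 10))


class TestReproducibleRegions:
    def test_chained_overlap(self):
        reps = [[iv("chr1", 100, 200)], [iv("chr1", 150, 250)],
                [iv("chr1", 180, 300)]]
        assert reproducible_regions(reps) == [iv("chr1", 100, 200)]

    def test_region_absent_in_one_replicate_dropped(self):
        reps = [[iv("chr1", 100, 200), iv("chr1", 500, 600)],
                [iv("chr1", 150, 250)],
                [iv("chr1", 180, 300), iv("chr1", 550, 650)]]
        assert reproducible_regions(reps) == [iv("chr1", 100, 200)]

    def test_identical_replicates_identity(self):
        rep = [iv("chr1", 10, 60), iv("chr2", 0, 450)]
        assert reproducible_regions([rep, rep, rep]) == sorted(rep)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            reproducible_regions([[iv("chr1", 0, 10)]])

    def test_one_bp_overlap_counts(self):
        reps = [[iv("chr1", 100, 200)], [iv("chr1", 199, 300)]]
        assert reproducible_regions(reps) == [iv("chr1", 100, 200)]

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(3):
            reps.append([iv("chr1", int(s), int(s) + int(l))
                         for s, l in zip(rng.integers(0, 5000, 30),
                                         rng.integers(1, 300, 30))])
        expected = [a for a in reps[0]
                    if all(any(overlap_bruteforce(a, b) for b in rep)
                           for rep in reps[1:])]
        assert reproducible_regions(reps) == sorted(expected)


class TestExtendToLength:
    def test_symmetric_extension(self):
        out = extend_to_length([iv("chr1", 1000, 1100)], 450)
        assert out == [iv("chr1", 825, 1275)]

    def test_clipped_at_zero_keeps_length(self):
        out = extend_to_length([iv("chr1", 0, 50)], 450)
        assert out == [iv("chr1", 0, 450)]

    def test_long_interval_unchanged(self):
        long = iv("chr1", 0, 600)
        assert extend_to_length([long], 450) == [long]

    def test_odd_remainder_goes_to_end_side(self):
        out = extend_to_length([iv("chr1", 1000, 1001)], 450)
        region = out[0]
        assert len(region) == 450
        assert (region.end - 1001) - (1000 - region.start) == 1

    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=1, max_value=1000))
    def test_output_at_least_min_of_input_and_target(self, start, length):
        out = extend_to_length([iv("chr1", start, start + length)], 450)[0]
        assert len(out) >= min(length, 450)


class TestAssignNearestGene:
    def _tss(self):
        return pd.DataFrame({
            "gene_id": ["near", "far"],
            "chrom": ["chr1", "chr1"],
            "tss": [5_000, 600_000],
            "strand": ["+", "-"],
        })

    def test_nearest_within_cap(self):
        out = assign_nearest_gene([iv("chr1", 9_900, 10_100)], self._tss())
        assert out[iv("chr1", 9_900, 10_100)] == "near"

    def test_no_tss_within_cap_unassigned(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [2_000_000], "strand": ["+"]})
        assert assign_nearest_gene([iv("chr1", 0, 100)], tss) == {}

    def test_boundary_is_inclusive(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                            "tss": [500_100], "strand": ["+"]})
        region = iv("chr1", 50, 150)  # midpoint 100, distance exactly 500 kb
        assert assign_nearest_gene([region], tss) == {region: "g"}

    def test_equidistant_tie_break_lexicographic(self):
        tss = pd.DataFrame({"gene_id": ["zeta", "alpha"],
                            "chrom": ["chr1", "chr1"],
                            "tss": [900, 1100], "strand": ["+", "+"]})
        region = iv("chr1", 950, 1050)  # midpoint 1000
        with pytest.warns(UserWarning, match="equidistant"):
            out = assign_nearest_gene([region], tss)
        assert out[region] == "alpha"

    def test_wrong_chromosome_ignored(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr2"],
                            "tss": [100], "strand": ["+"]})
        assert assign_nearest_gene([iv("chr1", 50, 150)], tss) == {}


class TestRegulatoryLoad:
    def test_counts_and_ranks(self):
        regions = {iv("chr1", i * 1000, i * 1000 + 100): gene
                   for i, gene in enumerate(["a", "a", "a", "b", "b", "c"])}
        table = regulatory_load(regions)
        assert table.counts["a"] == 3
        assert table.counts["b"] == 2
        assert table.ranks["a"] == 1.0
        assert table.ranks["c"] == 3.0

    def test_rank_ties_averaged(self):
        regions = {iv("chr1", i * 1000, i * 1000 + 100): gene
                   for i, gene in enumerate(["a", "a", "b", "b", "c"])}
        table = regulatory_load(regions)
        assert table.ranks["a"] == 1.5 and table.ranks["b"] == 1.5


class TestSelectHRL:
    def _table(self, counts):
        regions = {}
        pos = 0
        for gi, c in enumerate(counts):
            for _ in range(c):
                regions[iv("chr1", pos, pos + 10)] = f"g{gi:03d}"
                pos += 20
        return regulatory_load(regions)

    def test_top_decile_and_min_count(self):
        counts = [59] + [30] * 4 + [8] * 5 + [3] * 80 + [1] * 10
        table = self._table(counts)
        hrl = select_hrl(table, 0.10, 7)
        assert len(hrl) == 10
        assert all(table.counts[g] >= 7 for g in hrl)

    def test_all_below_min_count_empty(self):
        table = self._table([6, 5, 4, 3, 2, 1])
        assert select_hrl(table, 0.10, 7) == set()

    def test_ten_genes_top_decile_is_one(self):
        table = self._table(list(range(10, 0, -1)))
        assert select_hrl(table, 0.10, 7) == {"g000"}

    def test_monotone_in_count(self):
        # raising a selected gene's count never drops it from the set
        counts = [20, 15, 9, 8, 8, 3, 2, 2, 1, 1]
        base = select_hrl(self._table(counts), 0.2, 7)
        assert "g000" in base
        counts[0] += 5
        bumped = select_hrl(self._table(counts), 0.2, 7)
        assert "g000" in bumped
        # and raising above the boundary adds the gene
        counts2 = [20, 15, 9, 8, 8, 3, 2, 2, 1, 1]
        counts2[2] = 25
        assert "g002" in select_hrl(self._table(counts2), 0.2, 7)


class TestExpressionShift:
    def test_identical_samples(self):
        d, p = expression_shift([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated(self):
        d, p = expression_shift([10.0] * 5, [1.0] * 5)
        assert d == 1.0

    def test_one_sd_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        d, p = expression_shift(a, b)
        assert p < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expression_shift([], [1.0])


class TestBedIO:
    def test_round_trip(self, tmp_path):
        path = str(tmp_path / "x.bed")
        regions = [iv("chr2", 5, 100), iv("chr1", 0, 450)]
        write_bed(regions, path)
        assert read_bed(path) == sorted(regions)


class TestPipeline:
    def test_recovers_planted_loads(self):
        spec = fixtures.FixtureSpec(
            seed=3, gene_loads={"g1": 8, "g2": 3, "g3": 1}, jitter=10)
        replicates, tss = fixtures.simulate_peaks(spec)
        table = load_pipeline(replicates, tss)
        assert table.counts.to_dict() == {"g1": 8, "g2": 3, "g3": 1}

    def test_order_flag_swaps_steps(self):
        spec = fixtures.FixtureSpec(
            seed=3, gene_loads={"g1": 4, "g2": 2}, jitter=0)
        replicates, tss = fixtures.simulate_peaks(spec)
        a = load_pipeline(replicates, tss, extend_before_overlap=True)
        b = load_pipeline(replicates, tss, extend_before_overlap=False)
        assert a.counts.to_dict() == b.counts.to_dict()
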