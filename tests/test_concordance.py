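"""Mark/TAD/loop/conservation concordance scoring and the shuffled null."""

import numpy as np
import pytest
from scipy import stats

import synloop as sl
from synloop.concordance import (ConservationTrack, conservation_compare,
                                 ccre_overlap, cumulative_match,
                                 loop_representation, mark_concordance,
                                 rank_sum_test, shuffle_regions, tad_call,
                                 vista_overlap)
from synloop.intervals import GenomicInterval
from synloop.synteny import P_PLUS_E, SyntenicInteraction


def iv(s, e, chrom="chrT1"):
    return GenomicInterval(chrom, s, e)


def rec(rid, p_span, e_span, chrom="chrT1"):
    return SyntenicInteraction(
        source_lri_id=rid, synteny_class=P_PLUS_E, enhancer_state="active",
        human_promoter=iv(*p_span, chrom=chrom),
        human_enhancer=iv(*e_span, chrom=chrom))


class TestShuffleRegions:
    sizes = {"chrT1": 10_000, "chrT2": 5_000}

    def test_forced_placement_when_chrom_equals_region_length(self):
        null = shuffle_regions([iv(0, 10_000)], self.sizes, seed=1)
        assert null.regions[0] == iv(0, 10_000)

    def test_same_seed_reproduces_identical_null(self):
        regions = [iv(100, 400), iv(900, 1200, "chrT2")]
        a = shuffle_regions(regions, self.sizes, seed=9)
        b = shuffle_regions(regions, self.sizes, seed=9)
        assert a.regions == b.regions

    def test_chromosome_and_length_matched(self):
        regions = [iv(100, 400), iv(900, 1200, "chrT2")]
        null = shuffle_regions(regions, self.sizes, seed=3)
        for orig, placed in zip(regions, null.regions):
            assert placed.chrom == orig.chrom
            assert placed.length == orig.length
            assert placed.end <= self.sizes[placed.chrom]

    def test_region_longer_than_chromosome_fails(self):
        with pytest.raises(ValueError, match="longer than its chromosome"):
            shuffle_regions([iv(0, 20_000)], self.sizes, seed=0)

    def test_start_positions_uniform_by_chi_square(self):
        """10,000 placements of a 100 bp region on a 10 kb chromosome."""
        starts = []
        region = [iv(0, 100)]
        for s in range(10_000):
            starts.append(shuffle_regions(region, {"chrT1": 10_000},
                                          seed=s).regions[0].start)
        counts, _ = np.histogram(starts, bins=20, range=(0, 9_901))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestRankSum:
    def test_identical_vectors_give_null_statistic_and_p_one(self):
        stat, p = rank_sum_test([0.5] * 30, [0.5] * 30)
        assert stat == 30 * 30 / 2
        assert p == 1.0

    def test_separated_samples_reject_strongly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.9, 0.02, size=100)
        y = rng.normal(0.1, 0.02, size=100)
        _, p = rank_sum_test(x, y)
        assert p < 1e-4

    def test_small_samples_use_exact_enumeration(self):
        # n=3 vs 3, complete separation: two-sided exact p = 2/C(6,3) = 0.1
        _, p = rank_sum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestConservation:
    def test_region_mean_weights_partial_bins(self):
        track = ConservationTrack([("chrT1", 0, 100, 0.2),
                                   ("chrT1", 100, 200, 0.8)])
        # [50,150): 50 bases at 0.2 and 50 at 0.8
        assert track.region_mean(iv(50, 150)) == pytest.approx(0.5)
        # [150,250): 50 covered bases at 0.8, 50 uncovered scoring 0
        assert track.region_mean(iv(150, 250)) == pytest.approx(0.4)

    def test_planted_signal_rejects(self, default_world):
        w = default_world
        enh = list(w.target_enhancers().values())
        null = shuffle_regions(enh, w.target_chrom_sizes, seed=7)
        _, p, scores, null_scores = conservation_compare(
            enh, null, w.conservation_track)
        assert np.mean(scores) > 0.8 and np.mean(null_scores) < 0.2
        assert p < 1e-4

    def test_empty_regions_fail(self, default_world):
        with pytest.raises(ValueError):
            conservation_compare([], sl.ShuffleNull((), 0),
                                 default_world.conservation_track)


class TestMarkConcordance:
    enhancers = {"e1": iv(1000, 2000), "e2": iv(5000, 6000)}

    def test_overlap_of_49_bp_is_not_matched(self):
        layers = {("t1", "H3K4me1"): [iv(951, 1049)]}  # 49 bp inside e1
        records, summary = mark_concordance(self.enhancers, layers)
        assert not any(r.matched for r in records)
        assert summary["pct_matched"].iloc[0] == 0.0

    def test_fully_contained_co_peak_is_matched_active(self):
        layers = {("t1", "H3K4me1"): [iv(1100, 1400)],
                  ("t1", "H3K27Ac"): [iv(1100, 1400)]}
        records, _ = mark_concordance(self.enhancers, layers)
        by_id = {r.enhancer_id: r for r in records}
        assert by_id["e1"].matched and by_id["e1"].state_in_human == "active"
        assert by_id["e1"].coverage_fraction == pytest.approx(0.3)
        assert not by_id["e2"].matched

    def test_no_k27ac_layer_means_state_unknown(self):
        layers = {("t1", "H3K4me1"): [iv(1100, 1400)]}
        records, _ = mark_concordance(self.enhancers, layers)
        assert {r.state_in_human for r in records} == {"unknown"}

    def test_planted_sixty_percent_layer_scores_sixty(self):
        """A layer covering exactly 60% of enhancers yields 60.0%."""
        w = sl.build_world(sl.WorldConfig(
            seed=4, tissue_match_rates={"only": 0.6}, k27ac_tissues=()))
        enh = w.target_enhancers()
        _, summary = mark_concordance(enh, w.peak_layers)
        assert summary["pct_matched"].iloc[0] == pytest.approx(60.0)

    def test_real_match_rate_beats_shuffled_null(self, default_world):
        w = default_world
        enh = w.target_enhancers()
        _, real = mark_concordance(enh, w.peak_layers)
        null = shuffle_regions(list(enh.values()), w.target_chrom_sizes,
                               seed=5)
        _, shuf = mark_concordance(
            {f"n{i}": r for i, r in enumerate(null.regions)}, w.peak_layers)
        merged = real.merge(shuf, on="tissue", suffixes=("", "_null"))
        assert (merged["pct_matched"] >= merged["pct_matched_null"]).all()


class TestCumulativeMatch:
    def test_single_tissue_curve_is_its_count(self):
        curve = cumulative_match({"t": {"a", "b", "c"}})
        assert curve["cumulative_unique"].tolist() == [3]

    def test_disjoint_sets_add(self):
        curve = cumulative_match({"t1": {"a", "b", "c"},
                                  "t2": {"d", "e", "f", "g"}})
        assert curve["cumulative_unique"].tolist() == [3, 7]

    def test_nested_sets_plateau(self):
        curve = cumulative_match({"big": {"a", "b", "c", "d"},
                                  "small": {"a", "b"}})
        assert curve["cumulative_unique"].tolist() == [2, 4]

    def test_curve_is_nondecreasing_and_ends_at_union(self, default_world):
        w = default_world
        enh = w.target_enhancers()
        records, _ = mark_concordance(enh, w.peak_layers)
        sets = {}
        for r in records:
            if r.matched:
                sets.setdefault(r.tissue, set()).add(r.enhancer_id)
        curve = cumulative_match(sets)
        vals = curve["cumulative_unique"].tolist()
        assert vals == sorted(vals)
        assert vals[-1] == len(set().union(*sets.values()))


class TestTadCall:
    records = [rec("r1", (1000, 2000), (8000, 9000))]

    def test_single_containing_tad_is_intra(self):
        _, summary = tad_call(self.records, {"d": [iv(0, 1_000_000)]})
        assert summary["intra"].iloc[0] == 1

    def test_adjacent_tads_are_inter(self):
        calls, _ = tad_call(self.records,
                            {"d": [iv(0, 5000), iv(5000, 20_000)]})
        assert calls[0].status == "inter"

    def test_anchor_in_tad_gap_is_outside(self):
        calls, _ = tad_call(self.records, {"d": [iv(0, 5000)]})
        assert calls[0].status == "outside"

    def test_partial_containment_is_not_inside(self):
        # TAD clips the enhancer: strict full-containment reading
        calls, _ = tad_call(self.records, {"d": [iv(0, 8500)]})
        assert calls[0].status == "outside"

    def test_status_invariant_to_tad_order(self):
        tads = [iv(0, 5000), iv(5000, 20_000), iv(100, 12_000)]
        a, _ = tad_call(self.records, {"d": tads})
        b, _ = tad_call(self.records, {"d": tads[::-1]})
        assert a[0].status == b[0].status == "intra"

    def test_world_intra_rates_recovered(self, default_world,
                                         pipeline_records):
        _, records = pipeline_records
        _, summary = tad_call(records, default_world.tad_sets)
        # every planted intra record is found; never more than planted
        assert summary.attrs["intra_in_any_dataset"] <= 10
        assert (summary["intra"] + summary["inter"]
                + summary["outside"] == summary["n"]).all()


class TestLoopRepresentation:
    def test_exact_anchor_match_is_represented(self):
        r = rec("r1", (1000, 2000), (8000, 9000))
        hits, _ = loop_representation([r],
                                      {"d": [(iv(1000, 2000), iv(8000, 9000))]})
        assert hits["d"] == {"r1"}

    def test_swapped_orientation_still_represented(self):
        r = rec("r1", (1000, 2000), (8000, 9000))
        hits, _ = loop_representation([r],
                                      {"d": [(iv(8000, 9000), iv(1000, 2000))]})
        assert hits["d"] == {"r1"}

    def test_loop_touching_one_anchor_only_is_not_represented(self):
        r = rec("r1", (1000, 2000), (8000, 9000))
        hits, _ = loop_representation([r],
                                      {"d": [(iv(1000, 2000), iv(20_000, 21_000))]})
        assert hits["d"] == set()

    def test_union_counts_by_inclusion_exclusion(self):
        """30% per dataset with half the hits shared -> union = 45%."""
        records = [rec(f"r{i}", (i * 100_000 + 1000, i * 100_000 + 2000),
                       (i * 100_000 + 8000, i * 100_000 + 9000))
                   for i in range(20)]

        def loops_for(ids):
            return [(records[i].human_promoter, records[i].human_enhancer)
                    for i in ids]

        loop_sets = {"A": loops_for(range(0, 6)),       # r0..r5
                     "B": loops_for(range(3, 9))}       # r3..r8
        _, summary = loop_representation(records, loop_sets)
        total = summary.set_index("dataset")
        assert total.loc["A", "n_represented"] == 6
        assert total.loc["B", "n_represented"] == 6
        assert total.loc["TOTAL", "n_represented"] == 9
        assert total.loc["TOTAL", "pct_of_total"] == pytest.approx(45.0)


class TestSetOverlaps:
    def test_one_bp_ccre_contact_counts(self):
        table, summary = ccre_overlap({"e": iv(1000, 2000)},
                                      [(iv(1999, 2500), ("RGL",))])
        assert table["overlaps_ccre"].all()
        assert summary.attrs["pct_overlapping"] == 100.0

    def test_no_ccres_means_zero_everywhere(self):
        table, summary = ccre_overlap({"e": iv(1000, 2000)}, [])
        assert not table["overlaps_ccre"].any()
        assert summary.attrs["pct_overlapping"] == 0.0

    def test_planted_rate_recovered_exactly(self, default_world,
                                            pipeline_records):
        lris, _ = pipeline_records
        mouse_enh = {x.id: x.enhancer_anchor.interval for x in lris}
        _, summary = ccre_overlap(mouse_enh, default_world.ccres)
        expected = round(0.95 * len(mouse_enh)) / len(mouse_enh) * 100
        assert summary.attrs["pct_overlapping"] == pytest.approx(expected)

    def test_vista_positive_and_negative_reported_separately(self):
        table = vista_overlap(
            {"e1": iv(1000, 2000), "e2": iv(9000, 9500)},
            [(iv(1500, 1600), "positive"), (iv(9100, 9200), "negative")])
        t = table.set_index("enhancer_id")
        assert t.loc["e1", "positive_hit"] and not t.loc["e1", "negative_hit"]
        assert t.loc["e2", "negative_hit"] and not t.loc["e2", "positive_hit"]

    def test_vista_planted_rate_recovered(self, default_world,
                                          pipeline_records):
        _, records = pipeline_records
        enh = {r.source_lri_id: r.human_enhancer for r in records
               if r.synteny_class == P_PLUS_E}
        table = vista_overlap(enh, default_world.vista)
        assert int(table["positive_hit"].sum()) == round(0.2 * len(enh))
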