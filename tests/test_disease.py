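"""Variant overlap, motif disruption, CNV overlap and enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

import synloop as sl
from synloop.disease import (CNVRecord, PWM, RiskVariant, cnv_overlap,
                             enhancer_only_disruptions, gene_panel_join,
                             hypergeometric_enrichment,
                             score_motif_disruption, variants_in_enhancers)
from synloop.intervals import GenomicInterval
from synloop.synteny import (P_PLUS_E, RegionAnnotation, SyntenicInteraction)

from oracles import brute_motif_scores

import pandas as pd


def iv(s, e, chrom="chrT1"):
    return GenomicInterval(chrom, s, e)


def rec(rid, p_span, e_span, gene="geneX", chrom="chrT1"):
    return SyntenicInteraction(
        source_lri_id=rid, synteny_class=P_PLUS_E, enhancer_state="active",
        human_promoter=iv(*p_span, chrom=chrom),
        human_enhancer=iv(*e_span, chrom=chrom),
        promoter_annotation=RegionAnnotation("promoter", (gene,), False))


def variant(pos, ppa=0.1, rsid="rs1", chrom="chrT1", ref="A", alt="G"):
    return RiskVariant(rsid=rsid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                       trait="SCZ", ppa=ppa)


class TestVariantsInEnhancers:
    records = [rec("r1", (1000, 2000), (8000, 9000))]

    def test_variant_at_first_enhancer_base_hits(self):
        # enhancer [8000,9000) 0-based; 1-based position 8001 is base 8000
        hits = variants_in_enhancers([variant(8001)], self.records)
        assert len(hits) == 1
        assert hits["interaction_id"].iloc[0] == "r1"
        assert hits["connected_genes"].iloc[0] == "geneX"

    def test_variant_just_past_enhancer_end_misses(self):
        assert len(variants_in_enhancers([variant(9001)], self.records)) == 0
        assert len(variants_in_enhancers([variant(9000)], self.records)) == 1

    def test_ppa_exactly_at_threshold_is_excluded(self):
        hits = variants_in_enhancers([variant(8500, ppa=0.01)], self.records)
        assert len(hits) == 0
        hits = variants_in_enhancers([variant(8500, ppa=0.0101)], self.records)
        assert len(hits) == 1

    def test_output_invariant_to_variant_order(self):
        vs = [variant(8100, rsid="rs1"), variant(8200, rsid="rs2"),
              variant(8300, rsid="rs3")]
        a = variants_in_enhancers(vs, self.records)
        b = variants_in_enhancers(vs[::-1], self.records)
        assert a.equals(b)

    def test_five_variant_cluster_connected_to_one_gene(self):
        """Five variants in five enhancers sharing one promoter gene."""
        w = sl.build_world(sl.WorldConfig(
            seed=8, hub_enhancers=5, n_variants_in_enhancer=0,
            n_motif_lost=0, n_motif_gained=0))
        hub = [x for x in w.interactions if "h" in x.id.split("_")[1]]
        assert len(hub) == 5
        records = []
        variants = []
        for i, x in enumerate(hub):
            records.append(SyntenicInteraction(
                source_lri_id=x.id, synteny_class=P_PLUS_E,
                enhancer_state=x.truth_state,
                human_promoter=x.target_promoter,
                human_enhancer=x.target_enhancer,
                promoter_annotation=RegionAnnotation(
                    "promoter", (x.gene_id,), False)))
            te = x.target_enhancer
            variants.append(RiskVariant(
                rsid=f"rs{i}", chrom=te.chrom, pos=te.start + 50 + 1,
                ref="A", alt="C", trait="SCZ", ppa=0.2))
        hits = variants_in_enhancers(variants, records)
        assert len(hits) == 5
        assert hits["rsid"].nunique() == 5
        assert hits["interaction_id"].nunique() == 5
        assert set(hits["connected_genes"]) == {hub[0].gene_id}


def uniform_pwm(m=6):
    return PWM("U", "U", tuple((0.25,) * 4 for _ in range(m)))


def consensus_pwm(consensus, p=0.97):
    rows = []
    for b in consensus:
        row = [(1 - p) / 3] * 4
        row["ACGT".index(b)] = p
        rows.append(tuple(row))
    return PWM("C", "C", tuple(rows))


def make_fetch(seq, offset=0):
    def fetch(chrom, start, end):
        return seq[start - offset:end - offset]
    return fetch


class TestMotifDisruption:
    def test_uniform_matrix_is_neutral_for_any_variant(self):
        seq = "TTTTTTTTATTTTTTTT"
        v = variant(9, ref="A", alt="G", chrom="c")
        d = score_motif_disruption(v, make_fetch(seq), uniform_pwm(6))
        assert d.delta == pytest.approx(0.0)
        assert d.effect == "neutral"

    def test_hand_computed_consensus_example(self):
        """ACGT consensus at p=0.97, variant G->T at motif position 3.

        Per-position consensus term log2(0.98/0.25) ~ 1.9709 bits; the
        mismatch term log2(0.02/0.25) ~ -3.6439; best_ref ~ 7.8834,
        best_alt ~ 2.2687, delta ~ -5.6147 -> lost at threshold 1.
        The assertion is against the exact closed form.
        """
        from math import log2

        consensus_bit = log2(0.98 / 0.25)
        mismatch_bit = log2(0.02 / 0.25)
        pwm = consensus_pwm("ACGT", p=0.97)
        seq = "TTTACGTTTT"   # ACGT at offset 3; variant at the G (index 5)
        v = RiskVariant(rsid="rs9", chrom="c", pos=6, ref="G", alt="T",
                        trait="SCZ", ppa=0.2)
        d = score_motif_disruption(v, make_fetch(seq), pwm,
                                   effect_threshold=1.0, pseudocount=0.01)
        assert d.best_ref_score == pytest.approx(4 * consensus_bit, abs=1e-9)
        assert d.best_alt_score == pytest.approx(
            3 * consensus_bit + mismatch_bit, abs=1e-9)
        assert d.delta == pytest.approx(mismatch_bit - consensus_bit,
                                        abs=1e-9)
        assert d.delta == pytest.approx(-5.6147, abs=2e-4)
        assert d.effect == "lost"

    def test_reverse_complement_site_scores_identically(self):
        pwm = consensus_pwm("ACCGTA")
        fwd_seq = "TTTTTACCGTATTTTT"   # site at offset 5
        rc_seq = "TTTTTTACGGTTTTTT"    # reverse complement planted
        v_f = RiskVariant(rsid="f", chrom="c", pos=8, ref="C", alt="T",
                          trait="SCZ", ppa=0.2)
        v_r = RiskVariant(rsid="r", chrom="c", pos=10, ref="G", alt="A",
                          trait="SCZ", ppa=0.2)   # complement position
        d_f = score_motif_disruption(v_f, make_fetch(fwd_seq), pwm)
        d_r = score_motif_disruption(v_r, make_fetch(rc_seq), pwm)
        assert d_f.best_ref_score == pytest.approx(d_r.best_ref_score)
        assert d_f.best_alt_score == pytest.approx(d_r.best_alt_score)

    def test_ref_allele_mismatch_raises(self):
        seq = "TTTTTTTTATTTTTTTT"
        v = variant(9, ref="C", alt="G", chrom="c")
        with pytest.raises(ValueError, match="expected ref"):
            score_motif_disruption(v, make_fetch(seq), uniform_pwm(6))

    def test_matches_brute_force_on_random_triples(self):
        """Best-window scores equal the exhaustive scorer on 200 triples."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = int(rng.integers(4, 12))
            matrix = []
            for _i in range(m):
                row = rng.dirichlet(np.ones(4))
                matrix.append(tuple(row.tolist()))
            pwm = PWM("R", "R", tuple(matrix))
            seq = "".join(rng.choice(list("ACGT"), size=2 * m - 1))
            ref = seq[m - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = RiskVariant(rsid="rr", chrom="c", pos=m, ref=ref, alt=alt,
                            trait="I", ppa=0.2)
            d = score_motif_disruption(v, make_fetch(seq), pwm,
                                       pseudocount=0.01)
            alt_seq = seq[:m - 1] + alt + seq[m:]
            ref_best, alt_best = brute_motif_scores(seq, alt_seq, matrix, 0.01)
            assert d.best_ref_score == pytest.approx(ref_best, abs=1e-9)
            assert d.best_alt_score == pytest.approx(alt_best, abs=1e-9)

    def test_planted_world_calls_recovered(self, default_world):
        """Planted lost/gained sites are called with the right sign."""
        w = default_world
        truth = w.variant_truth
        planted = truth[truth["planted_effect"] != ""]
        pwms = {p.motif_id: p for p in w.pwms}
        by_rsid = {v.rsid: v for v in w.variants}
        for row in planted.itertuples(index=False):
            d = score_motif_disruption(by_rsid[row.rsid],
                                       w.target_genome.fetch,
                                       pwms[row.motif_id])
            assert d.effect == row.planted_effect


class TestCnvOverlap:
    records = [rec("r1", (1000, 2000), (8000, 9000))]

    def cnv(self, s, e, cohort="case", cnv_type="loss"):
        return CNVRecord(interval=iv(s, e), cnv_type=cnv_type, cohort=cohort,
                         subject_id="s1")

    def test_identical_interval_sets_both_flags(self):
        table = cnv_overlap([self.cnv(500, 9500)], self.records)
        assert len(table) == 1
        assert table["overlaps_enhancer"].iloc[0]
        assert table["overlaps_promoter"].iloc[0]

    def test_cnv_in_gene_desert_produces_no_rows(self):
        assert len(cnv_overlap([self.cnv(50_000, 60_000)], self.records)) == 0

    def test_enhancer_only_excludes_promoter_covering_cnv(self):
        cnvs = [self.cnv(500, 9500), self.cnv(8100, 8200)]
        table = cnv_overlap(cnvs, self.records)
        eo = enhancer_only_disruptions(table, cnvs)
        assert eo["cnv_index"].tolist() == [1]
        assert eo["case_exclusive"].iloc[0]

    def test_control_mirror_clears_case_exclusive(self):
        cnvs = [self.cnv(8100, 8600),
                self.cnv(8200, 8700, cohort="control")]   # 80% reciprocal
        table = cnv_overlap(cnvs, self.records)
        eo = enhancer_only_disruptions(table, cnvs)
        case_rows = eo[eo["cohort"] == "case"]
        assert len(case_rows) == 1
        assert not case_rows["case_exclusive"].iloc[0]

    def test_control_of_other_type_does_not_clear_exclusivity(self):
        cnvs = [self.cnv(8100, 8600, cnv_type="loss"),
                self.cnv(8100, 8600, cohort="control", cnv_type="gain")]
        table = cnv_overlap(cnvs, self.records)
        eo = enhancer_only_disruptions(table, cnvs)
        assert eo[eo["cohort"] == "case"]["case_exclusive"].iloc[0]


class TestHypergeometricEnrichment:
    records = [rec("r1", (1000, 2000), (8000, 9000))]

    def in_region(self, n, cohort):
        return [CNVRecord(iv(8000, 9000), "loss", cohort, subject_id=str(i))
                for i in range(n)]

    def out_region(self, n, cohort):
        return [CNVRecord(iv(50_000, 51_000), "loss", cohort,
                          subject_id=str(i)) for i in range(n)]

    def test_exact_tail_example(self):
        # N=20, K=10, n=10, k=9 -> (10*10 + 1)/C(20,10)
        case = self.in_region(9, "case") + self.out_region(1, "case")
        control = self.in_region(1, "control") + self.out_region(9, "control")
        r = hypergeometric_enrichment(case, control, self.records)
        assert (r.k, r.n, r.K, r.N) == (9, 10, 10, 20)
        expected = float(Fraction(10 * 10 + 1, comb(20, 10)))
        assert r.p_value == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.466e-4, rel=1e-3)

    def test_proportional_cohorts_are_not_enriched(self):
        case = self.in_region(5, "case") + self.out_region(5, "case")
        control = self.in_region(5, "control") + self.out_region(5, "control")
        r = hypergeometric_enrichment(case, control, self.records)
        assert r.p_value >= 0.5

    def test_degenerate_margins_give_p_one(self):
        r = hypergeometric_enrichment(self.out_region(5, "case"),
                                      self.out_region(5, "control"),
                                      self.records)
        assert r.K == 0 and r.p_value == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], self.out_region(3, "control"),
                                      self.records)

    def test_planted_odds_ratio_five_rejects(self, default_world,
                                             pipeline_records):
        _, records = pipeline_records
        r = hypergeometric_enrichment(default_world.cnv_case,
                                      default_world.cnv_control, records)
        assert r.p_value < 1e-4

    def test_planted_enrichment_rejects_across_seeds(self):
        """Odds ratio 5 cohorts reject at p<0.01 in >=90% of replicates."""
        world = sl.build_world(sl.WorldConfig(seed=43))
        lris = sl.prepare_interactions(
            world.anchor_pairs, world.genes_source,
            world.source_k4me1, world.source_k27ac)
        records = sl.map_interactions(lris, sl.ChainIndex(world.chain_set))
        n_reject = 0
        n_rep = 30
        for s in range(n_rep):
            sl.plant_cnv_enrichment(world, odds_ratio=5.0,
                                    n_case=500, n_control=500, seed=7000 + s)
            r = hypergeometric_enrichment(world.cnv_case,
                                          world.cnv_control, records)
            if r.p_value < 0.01:
                n_reject += 1
        assert n_reject >= 0.9 * n_rep

    def test_recorded_table_marginals(self, default_world):
        t = default_world.cnv_table
        assert t["case_total"] == 500 and t["control_total"] == 500
        assert 0 <= t["case_overlap"] <= 500


class TestGenePanelJoin:
    panels = {"DD": pd.DataFrame({"gene_id": ["g1", "g1", "g2"],
                                  "confidence": ["strong", "limited",
                                                 "definitive"]})}

    def test_matched_gene_gets_its_class(self):
        out = gene_panel_join(["g2"], self.panels)
        assert out["confidence"].tolist() == ["definitive"]

    def test_absent_gene_is_unknown(self):
        out = gene_panel_join(["g9"], self.panels)
        assert out["confidence"].tolist() == ["unknown"]

    def test_duplicate_panel_rows_are_preserved(self):
        out = gene_panel_join(["g1"], self.panels)
        assert sorted(out["confidence"]) == ["limited", "strong"]
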