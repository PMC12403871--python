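"""TSS calling, merging, classification and promoter-context statistics."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import single_linkage_clusters
from tul.io_formats import EndCountProfile, GeneFeature, GenomeAnnotation, GenomeSequence, LibraryMeta
from tul.sites import CalledSite, merge_sites
from tul.tss_mapper import (
    TSSRecord,
    base_composition,
    call_tss,
    category_counts,
    classify_tss,
    utr5_and_leaderless,
)


def _pair(enr_counts, une_counts, strand="+"):
    meta = LibraryMeta("dRNA", "NMS", 1, enriched=True)
    a = EndCountProfile("c1", strand, enr_counts, meta=meta, contig_length=5000)
    b = EndCountProfile("c1", strand, une_counts,
                        meta=LibraryMeta("dRNA", "NMS", 1, enriched=False),
                        contig_length=5000)
    return a, b


class TestCallTss:
    def test_enrichment_rule_with_pseudocount(self):
        # 20 vs 5: (20+1)/(5+1) = 3.5 >= 2 -> called
        a, b = _pair({100: 20.0}, {100: 5.0})
        assert [s.position for s in call_tss(a, b)] == [100]
        # 20 vs 15: 21/16 < 2 -> rejected
        a, b = _pair({100: 20.0}, {100: 15.0})
        assert call_tss(a, b) == []

    def test_height_threshold(self):
        a, b = _pair({100: 9.0}, {})
        assert call_tss(a, b) == []

    def test_local_maximum_with_five_prime_tie_break(self):
        a, b = _pair({100: 15.0, 101: 20.0, 102: 20.0}, {})
        called = call_tss(a, b)
        assert [s.position for s in called] == [101]
        # on the minus strand the 5'-most of the tie is the larger coordinate
        a, b = _pair({100: 15.0, 101: 20.0, 102: 20.0}, {}, strand="-")
        assert [s.position for s in call_tss(a, b)] == [102]

    def test_mismatched_profiles_rejected(self):
        a, _ = _pair({100: 20.0}, {})
        _, b = _pair({}, {}, strand="-")
        with pytest.raises(ValueError):
            call_tss(a, b)

    def test_strand_mirror_symmetry(self):
        """Mirroring the genome maps called sites via p -> L-1-p."""
        L = 5000
        enr = {100: 15.0, 101: 20.0, 102: 20.0, 500: 30.0, 600: 12.0}
        une = {500: 20.0}
        a, b = _pair(enr, une, strand="+")
        fw = call_tss(a, b)
        am = EndCountProfile("c1", "-", {L - 1 - p: c for p, c in enr.items()},
                            meta=a.meta, contig_length=L)
        bm = EndCountProfile("c1", "-", {L - 1 - p: c for p, c in une.items()},
                            meta=b.meta, contig_length=L)
        rv = call_tss(am, bm)
        assert sorted(L - 1 - s.position for s in rv) == sorted(s.position for s in fw)


class TestMergeSites:
    def _sites(self, positions, condition, strand="+", height=10.0):
        return [CalledSite(p, strand, height, condition) for p in positions]

    def test_sites_within_window_merge(self):
        merged = merge_sites(
            [self._sites([100], "NMS"), self._sites([104], "ANMS")],
            all_conditions=["NMS", "ANMS"],
        )
        assert len(merged) == 1
        assert merged[0].conditions == ("NMS", "ANMS")
        assert merged[0].constitutive

    def test_sites_past_window_stay_separate(self):
        merged = merge_sites(
            [self._sites([100], "NMS"), self._sites([106], "ANMS")],
            all_conditions=["NMS", "ANMS"],
        )
        assert len(merged) == 2

    def test_chain_merges_by_single_linkage(self):
        """100,105,110 chain collapses to one site at the max-height member."""
        lists = [
            [CalledSite(100, "+", 5.0, "NMS"),
             CalledSite(105, "+", 20.0, "NMS"),
             CalledSite(110, "+", 8.0, "NMS")]
        ]
        merged = merge_sites(lists, all_conditions=["NMS"])
        oracle = single_linkage_clusters([100, 105, 110], window=5)
        assert len(oracle) == 1
        assert len(merged) == 1
        assert merged[0].position == 105

    def test_matches_clustering_oracle_on_random_input(self):
        rng = np.random.default_rng(31)
        positions = sorted(set(rng.integers(0, 2000, size=60).tolist()))
        lists = [[CalledSite(p, "+", float(rng.integers(5, 50)), "NMS")
                  for p in positions]]
        merged = merge_sites(lists, all_conditions=["NMS"])
        assert len(merged) == len(single_linkage_clusters(positions, 5))

    def test_idempotence(self):
        rng = np.random.default_rng(32)
        positions = sorted(set(rng.integers(0, 3000, size=80).tolist()))
        lists = [[CalledSite(p, "+", float(rng.integers(5, 50)), "NMS")
                  for p in positions]]
        once = merge_sites(lists, all_conditions=["NMS"])
        again = merge_sites(
            [[CalledSite(m.position, m.strand, m.height, m.conditions[0])
              for m in once]],
            all_conditions=["NMS"],
        )
        assert [m.position for m in again] == [m.position for m in once]


def _merged(position, strand="+", height=10.0, conditions=("NMS",)):
    from tul.sites import MergedSite

    return MergedSite(position, strand, tuple(conditions), height, 5.0, False)


class TestClassifyTss:
    def test_lone_upstream_site_is_primary(self, toy_annotation):
        recs = classify_tss([_merged(950)], toy_annotation)
        assert recs[0].category == "P"
        assert recs[0].assigned_gene == "geneA"

    def test_weaker_competitor_is_secondary(self, toy_annotation):
        recs = classify_tss(
            [_merged(950, height=50.0), _merged(940, height=10.0)], toy_annotation
        )
        by_pos = {r.position: r.category for r in recs}
        assert by_pos == {950: "P", 940: "S"}

    def test_antisense_site_inside_gene_body(self, toy_annotation):
        recs = classify_tss([_merged(1500, strand="-")], toy_annotation)
        assert recs[0].category == "A"

    def test_sense_site_inside_gene_body_is_internal(self, toy_annotation):
        recs = classify_tss([_merged(1500, strand="+")], toy_annotation)
        assert recs[0].category == "I"

    def test_orphan_site_is_intergenic(self, toy_annotation):
        recs = classify_tss([_merged(4900)], toy_annotation)
        assert recs[0].category == "N"

    def test_minus_strand_gene_upstream_window(self, toy_annotation):
        # geneB spans [3000, 3600) on '-': upstream means positions >= 3599
        recs = classify_tss([_merged(3700, strand="-")], toy_annotation)
        assert recs[0].category == "P"
        assert recs[0].assigned_gene == "geneB"

    def test_every_site_gets_exactly_one_category(self, toy_annotation):
        rng = np.random.default_rng(33)
        sites = [
            _merged(int(p), strand=("+" if rng.random() < 0.5 else "-"))
            for p in rng.integers(0, 4999, size=50)
        ]
        recs = classify_tss(sites, toy_annotation)
        counts = category_counts(recs)
        assert sum(counts.values()) == len(sites)


class TestUtr5:
    def test_utr_length_arithmetic(self, toy_annotation):
        recs = classify_tss([_merged(937)], toy_annotation)
        recs, summary = utr5_and_leaderless(recs, toy_annotation)
        assert recs[0].utr5_length == 63
        assert not recs[0].leaderless
        assert summary["median_utr5"] == 63.0

    def test_leaderless_boundary_is_strict(self, toy_annotation):
        zero = classify_tss([_merged(1000)], toy_annotation)
        zero, _ = utr5_and_leaderless(zero, toy_annotation)
        assert zero[0].utr5_length == 0 and zero[0].leaderless
        ten = classify_tss([_merged(990)], toy_annotation)
        ten, _ = utr5_and_leaderless(ten, toy_annotation)
        assert ten[0].utr5_length == 10 and not ten[0].leaderless


class TestBaseComposition:
    def test_uniform_base_gives_unit_frequency(self):
        genome = "A" * 50 + "G" + "A" * 49
        sites = [TSSRecord(50, "+", ("NMS",), 10.0, 5.0, "N")]
        freq = base_composition(sites, genome, flank=2)
        assert freq.loc[0, "G"] == 1.0
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_minus_strand_reverse_complemented(self):
        genome = "T" * 100
        sites = [TSSRecord(50, "-", ("NMS",), 10.0, 5.0, "N")]
        freq = base_composition(sites, genome, flank=1)
        assert freq.loc[0, "A"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            base_composition([], "ACGT" * 100)

    def test_planted_purine_bias_recovered(self, study, default_config):
        annotation, truth, _ = study
        seq = annotation.sequences["chr"].sequence
        sites = [
            TSSRecord(s.position, s.strand, s.conditions, 10.0, 5.0, "N")
            for s in truth.tss
        ]
        freq = base_composition(sites, seq, flank=2)
        purine = freq.loc[0, "A"] + freq.loc[0, "G"]
        n = len(sites)
        sd = np.sqrt(0.9 * 0.1 / n)
        assert purine == pytest.approx(default_config.tss_purine_bias, abs=3 * sd)
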