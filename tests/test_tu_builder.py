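"""TU assembly, categorization and COG functional-relatedness statistic."""

from __future__ import annotations

import numpy as np
import pytest

from tul.io_formats import GeneFeature, GenomeAnnotation, GenomeSequence
from tul.synthetic_data import SimulationConfig, simulate_genome
from tul.tep_mapper import TEPRecord
from tul.tss_mapper import TSSRecord
from tul.tu_builder import (
    assemble_tus,
    categorize_and_summarize,
    functional_enrichment_score,
    random_neighbor_baseline,
)


def _tss(position, strand="+", category="P", gene=None, height=50.0,
         conditions=("NMS",)):
    return TSSRecord(
        position=position, strand=strand, conditions=tuple(conditions),
        height=height, enrichment=5.0, category=category, assigned_gene=gene,
    )


def _tep(position, strand="+", category="P", gene=None, conditions=("NMS",)):
    return TEPRecord(
        position=position, strand=strand, conditions=tuple(conditions),
        height=30.0, category=category, assigned_gene=gene,
    )


def _annotation(genes):
    seq = GenomeSequence("c1", "ACGT" * 2500)
    return GenomeAnnotation(sequences={"c1": seq}, genes=list(genes))


class TestAssembleTus:
    def test_single_gene_becomes_monocistronic(self):
        ann = _annotation([GeneFeature("g1", "c1", 1000, 2000, "+")])
        tus = assemble_tus(
            [_tss(950, gene="g1")], [_tep(2100, gene="g1")], ann
        )
        assert len(tus) == 1
        assert tus[0].category == "monocistronic"
        assert tus[0].genes == ("g1",)
        assert tus[0].span == (950, 2101)

    def test_two_genes_become_polycistronic(self):
        ann = _annotation([
            GeneFeature("g1", "c1", 1000, 1400, "+"),
            GeneFeature("g2", "c1", 1450, 2000, "+"),
        ])
        tus = assemble_tus([_tss(950, gene="g1")], [_tep(2100, gene="g2")], ann)
        assert tus[0].category == "polycistronic"
        assert tus[0].genes == ("g1", "g2")

    def test_utr_internal_tep_gives_cis_regulatory_tu(self):
        ann = _annotation([GeneFeature("g1", "c1", 1000, 2000, "+")])
        tus = assemble_tus(
            [_tss(937, gene="g1")], [_tep(980, category="C")], ann
        )
        assert tus[0].category == "cis_regulatory"
        assert tus[0].genes == ()

    def test_minus_strand_pairing(self):
        ann = _annotation([GeneFeature("g1", "c1", 3000, 3600, "-")])
        tus = assemble_tus(
            [_tss(3700, strand="-", gene="g1")],
            [_tep(2900, strand="-", gene="g1")],
            ann,
        )
        assert len(tus) == 1
        assert tus[0].category == "monocistronic"
        assert tus[0].span == (2900, 3701)

    def test_tep_beyond_max_span_leaves_tss_unpaired(self):
        ann = _annotation([GeneFeature("g1", "c1", 1000, 2000, "+")])
        tus = assemble_tus(
            [_tss(950, gene="g1")], [_tep(9000, category="N")], ann, max_span=5000
        )
        assert tus == []

    def test_cross_condition_merge_unions_conditions(self):
        ann = _annotation([GeneFeature("g1", "c1", 1000, 2000, "+")])
        tss = [
            _tss(950, gene="g1", conditions=("NMS",)),
            _tss(953, gene="g1", category="S", conditions=("ANMS",), height=20.0),
        ]
        tep = [_tep(2100, gene="g1", conditions=("NMS", "ANMS"))]
        tus = assemble_tus(tss, tep, ann)
        assert len(tus) == 1
        assert set(tus[0].conditions) == {"NMS", "ANMS"}

    def test_genes_fully_contained_only(self, pipeline_result, study):
        annotation, _, _ = study
        gene_by_id = {g.gene_id: g for g in annotation.genes}
        for tu in pipeline_result.tus:
            lo, hi = tu.span
            for gid in tu.genes:
                g = gene_by_id[gid]
                assert lo <= g.start and g.end <= hi


class TestCategorize:
    def test_counts_partition_and_median(self):
        ann = _annotation([
            GeneFeature("g1", "c1", 1000, 1400, "+"),
            GeneFeature("g2", "c1", 1450, 1800, "+"),
        ])
        tus = assemble_tus(
            [_tss(950, gene="g1")], [_tep(1900, gene="g2")], ann
        )
        summary = categorize_and_summarize(tus)
        assert sum(summary["counts"].values()) == summary["n_total"]

    def test_median_genes_per_polycistronic(self):
        sizes = {2: None, 3: None, 5: None}

        class FakeTU:
            def __init__(self, n):
                self.category = "polycistronic"
                self.genes = tuple(f"g{i}" for i in range(n))

        summary = categorize_and_summarize([FakeTU(n) for n in sizes])
        assert summary["median_genes_per_polycistronic"] == 3.0


class TestEnrichmentScore:
    def test_formula_cases(self):
        cog = {"a": "M", "b": "M", "c": "D", "d": "C", "e": "C", "f": "C",
               "g": "N", "h": None}
        assert functional_enrichment_score(["a", "b", "c"], cog).score == 1.0
        assert functional_enrichment_score(["d", "e", "f"], cog).score == 3.0
        assert functional_enrichment_score(
            ["a", "c", "g"], cog
        ).score == pytest.approx(1 / 3)

    def test_unannotated_genes_excluded(self):
        cog = {"a": "M", "b": None}
        es = functional_enrichment_score(["a", "b"], cog)
        assert es.n_genes_with_cog == 1
        assert functional_enrichment_score(["b"], cog) is None

    def test_per_gene_mode_bounded_by_one(self):
        cog = {"d": "C", "e": "C", "f": "C"}
        es = functional_enrichment_score(["d", "e", "f"], cog, mode="per-gene")
        assert es.score == 1.0


class TestRandomBaseline:
    def test_fixed_seed_is_deterministic(self, study):
        annotation, truth, _ = study
        kwargs = dict(
            tu_sizes=[2, 3], observed_scores=[1.0, 2.0], n_draws=50, seed=11
        )
        r1 = random_neighbor_baseline(annotation, **kwargs)
        r2 = random_neighbor_baseline(annotation, **kwargs)
        assert r1["baseline_scores"] == r2["baseline_scores"]

    def test_identical_distributions_are_not_significant(self, study):
        annotation, _, _ = study
        res = random_neighbor_baseline(
            annotation, tu_sizes=[2, 3], observed_scores=[], n_draws=60, seed=5
        )
        res2 = random_neighbor_baseline(
            annotation,
            tu_sizes=[2, 3],
            observed_scores=res["baseline_scores"],
            n_draws=60,
            seed=5,
        )
        assert res2["p"] > 0.9  # same multiset up to tie correction

    def test_planted_operons_score_above_random_neighbors(self):
        """Co-transcribed operon genes share COG categories; random
        neighbor runs straddling TU boundaries do not."""
        cfg = SimulationConfig(
            seed=7, genome_length=600_000, n_genes=360, operon_fraction=0.75
        )
        annotation, truth = simulate_genome(cfg)
        cog = {g.gene_id: g.cog_category for g in annotation.genes}
        observed = []
        sizes = []
        for tu in truth.tus:
            if len(tu.gene_ids) < 2:
                continue
            es = functional_enrichment_score(list(tu.gene_ids), cog)
            if es:
                observed.append(es.score)
                sizes.append(len(tu.gene_ids))
        assert len(observed) >= 100
        res = random_neighbor_baseline(
            annotation, sizes, observed, n_draws=500, seed=7
        )
        assert res["observed_median"] > res["baseline_median"]
        assert res["p"] < 0.01
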