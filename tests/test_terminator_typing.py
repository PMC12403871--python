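"""HS/LS split, U-content typing, enrichment matrices and readthrough."""

from __future__ import annotations

import numpy as np
import pytest

from tul.io_formats import EndCountProfile
from tul.rnafold import fold_window
from tul.sites import MergedSite
from tul.tep_mapper import TEPRecord
from tul.terminator_typing import (
    positional_enrichment,
    readthrough_fraction,
    shape_counts,
    split_hs_ls,
    stem_loop_metrics,
    type_u_content,
    upstream_window_seq,
)


def _tep(position, strand="+", fold=None, shape=None, category="N"):
    return TEPRecord(
        position=position, strand=strand, conditions=("NMS",), height=20.0,
        category=category, fold=fold, shape=shape,
    )


def _folded_tep(genome, position, strand="+"):
    seq = upstream_window_seq(genome, position, strand)
    return _tep(position, strand, fold=fold_window(seq, expected_length=40))


# a strong GC hairpin whose stem closes 10 nt before the window's 3' end
STEM = "GGGGCCGGCC"
HAIRPIN = STEM + "GAAA" + "GGCCGGCCCC"  # stem + loop + revcomp(stem)


def _genome_with_terminator(downstream10: str, lead="A" * 60) -> tuple[str, int]:
    """Genome string with the hairpin then `downstream10`; TEP at its end."""
    genome = lead + HAIRPIN + downstream10 + "A" * 60
    tep_pos = len(lead) + len(HAIRPIN) + len(downstream10) - 1
    return genome, tep_pos


class TestSplitHsLs:
    def _records(self, dgs):
        out = []
        for i, dg in enumerate(dgs):
            n = max(3, int(-dg // 3))
            fold = fold_window("A" * 40)
            object.__setattr__(fold, "delta_g", float(dg))
            out.append(_tep(100 + i * 50, fold=fold))
        return out

    def test_threshold_inclusive_on_hs_side(self):
        recs = self._records([-19.0, -10.0])
        labeled, thr = split_hs_ls(recs, threshold=-19.0)
        assert thr == -19.0
        assert labeled[0].shape is None  # HS, awaiting U typing
        assert labeled[1].shape == "LS"

    def test_median_mode_matches_stated_rule(self):
        labeled, thr = split_hs_ls(self._records([-30, -20, -10, -5]), "median")
        assert thr == -15.0
        shapes = [r.shape for r in labeled]
        assert shapes == [None, None, "LS", "LS"]

    def test_median_mode_odd_count_puts_majority_in_hs(self):
        labeled, thr = split_hs_ls(self._records([-30, -20, -10]), "median")
        n_hs = sum(1 for r in labeled if r.shape is None)
        assert n_hs == 2  # ceil(3/2) by <= inclusivity

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_hs_ls([], "median")


class TestTypeUContent:
    @pytest.mark.parametrize(
        "downstream,lead,expected_label,expected_u",
        [
            # leads end in a base that cannot stack-extend the hairpin onto
            # the downstream tract, keeping the stem anchor unambiguous
            ("TTTAGCACGA", "A" * 59 + "C", "HS_U_RICH", 3),
            ("GCGCGCGCGC", "A" * 60, "HS_U_LACK", 0),
            ("TTAGGGGGGG", "A" * 59 + "C", "HS_U_LACK", 2),
        ],
    )
    def test_u_counting_rules(self, downstream, lead, expected_label, expected_u):
        genome, pos = _genome_with_terminator(downstream, lead=lead)
        rec = _folded_tep(genome, pos)
        assert rec.fold.hairpin3 is not None
        typed = type_u_content(rec, genome)
        assert typed.shape == expected_label
        assert typed.u_count == expected_u

    def test_minus_strand_counts_on_transcript(self):
        downstream = "TTTTAGCACG"
        genome_fw, pos = _genome_with_terminator(downstream, lead="A" * 59 + "C")
        # place the same transcript on the minus strand
        from tul.io_formats import revcomp

        genome_rc = revcomp(genome_fw)
        pos_rc = len(genome_fw) - 1 - pos
        rec = _folded_tep(genome_rc, pos_rc, strand="-")
        typed = type_u_content(rec, genome_rc)
        assert typed.shape == "HS_U_RICH"
        assert typed.u_count == 4

    def test_ls_records_pass_through(self):
        rec = _tep(100, shape="LS")
        assert type_u_content(rec, "A" * 200) is rec

    def test_hs_record_without_hairpin_is_inconsistent(self):
        rec = _tep(100, fold=fold_window("A" * 40))
        with pytest.raises(ValueError):
            type_u_content(rec, "A" * 200)


class TestShapeAccounting:
    def test_shape_counts_partition(self, pipeline_result):
        recs = pipeline_result.tep_records
        counts = shape_counts(recs)
        n_hs = counts["HS_U_RICH"] + counts["HS_U_LACK"]
        n_total = n_hs + counts["LS"]
        assert n_total == len([r for r in recs if r.shape is not None])
        # median split: HS gets ceil(n/2)
        assert n_hs == (n_total + 1) // 2

    def test_u_count_bounded_by_window(self, pipeline_result):
        for r in pipeline_result.tep_records:
            if r.u_count is not None:
                assert 0 <= r.u_count <= 10


class TestPositionalEnrichment:
    def test_matrix_shape_and_row_sums(self, study, pipeline_result):
        annotation, _, _ = study
        mats = positional_enrichment(pipeline_result.tep_records, annotation)
        for mat in mats.values():
            assert mat.shape == (101, 4)
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_u_tract_enriched_at_l_shaped_teps(self, study, pipeline_result):
        annotation, _, _ = study
        seq = annotation.sequences["chr"].sequence
        background_t = seq.count("T") / len(seq)
        mats = positional_enrichment(pipeline_result.tep_records, annotation)
        near = mats["HS_U_RICH"].loc[-5:5, "T"].mean()
        assert near > background_t


class TestReadthrough:
    def _cov(self, counts, strand="+"):
        return EndCountProfile("c1", strand, counts, contig_length=2000)

    def test_ratio_arithmetic(self):
        up = {p: 10.0 for p in range(801, 1001)}
        down = {p: 2.0 for p in range(1001, 1201)}
        cov = self._cov({**up, **down})
        recs, _ = readthrough_fraction(
            [_tep(1000, shape="LS")], cov, self._cov({}, "-")
        )
        assert recs[0].readthrough == pytest.approx(0.2)

    def test_flat_coverage_gives_unity(self):
        cov = self._cov({p: 7.0 for p in range(500, 1500)})
        recs, _ = readthrough_fraction(
            [_tep(1000, shape="LS")], cov, self._cov({}, "-")
        )
        assert recs[0].readthrough == pytest.approx(1.0)

    def test_zero_upstream_is_excluded_not_divided(self):
        cov = self._cov({p: 3.0 for p in range(1001, 1201)})
        recs, summary = readthrough_fraction(
            [_tep(1000, shape="LS")], cov, self._cov({}, "-")
        )
        assert recs[0].readthrough is None
        assert summary["n_undefined"] == 1

    def test_simulated_class_ordering(self, pipeline_result):
        per_class = pipeline_result.readthrough_summary["per_class"]
        assert (
            per_class["HS_U_RICH"]["median"]
            < per_class["HS_U_LACK"]["median"]
            < per_class["LS"]["median"]
        )


class TestStemLoopMetrics:
    def test_distributions_and_comparisons(self, pipeline_result):
        res = stem_loop_metrics(pipeline_result.tep_records)
        hs_stems = res["distributions"]["HS_U_RICH"]["stem"]
        assert hs_stems and min(hs_stems) >= 2
        key = "HS_U_LACK_vs_LS_stem"
        comp = res["comparisons"][key]
        if "skipped" not in comp:
            assert 0 <= comp["p"] <= 1
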