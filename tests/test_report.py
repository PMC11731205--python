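"""Class summaries, sensitivity percentages, histograms and strata."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tissense.antigen_matcher import DetectionMatrix
from tissense.orf_builder import ORFCall
from tissense.report import (
    class_summary,
    detection_histogram,
    expression_strata,
    matrix_from_class_counts,
    percentage,
    round_pct,
    sensitivity,
)


def _call(i, cls="annotated", sample="S1", length=10, gene=None):
    return ORFCall(
        transcript_id=f"T{i}",
        gene_id=gene or f"G{i}",
        tis_position=0,
        stop_position=3 * length,
        length_aa=length,
        peptide="M" * length,
        complete=True,
        orf_class=cls,
        sample_id=sample,
    )


def test_rounding_is_half_away_from_zero():
    assert round_pct(63.57) == 63.6
    assert round_pct(63.55) == 63.6  # not banker's rounding
    assert round_pct(20.04) == 20.0
    assert percentage(82, 129) == 63.6
    assert percentage(70, 95) == 73.7


class TestClassSummary:
    def test_single_call_counts_one_everywhere(self):
        s = class_summary({"S1": [_call(0, "upstream")]})
        assert s.union.loc["upstream", "n_tis"] == 1
        assert s.union.loc["upstream", "n_genes"] == 1
        assert s.union.loc["upstream", "mean_orf_length_aa"] == 10
        assert s.per_sample.loc[("S1", "upstream"), "n_tis"] == 1

    def test_union_deduplicates_shared_tis_and_tallies_match_recount(self):
        calls_s1 = [_call(i, "annotated", "S1") for i in range(4)]
        calls_s2 = [_call(i, "annotated", "S2") for i in range(2, 6)]
        calls_s2 += [_call(9, "upstream", "S2", length=7)]
        s = class_summary({"S1": calls_s1, "S2": calls_s2})
        assert s.union.loc["annotated", "n_tis"] == 6  # T0..T5 deduplicated
        assert s.union.loc["upstream", "n_tis"] == 1
        per_sample_total = s.per_sample.loc["S2", "n_tis"].sum()
        assert per_sample_total == 5
        assert int(s.union["n_tis"].sum()) >= per_sample_total

    def test_incomplete_orfs_excluded_from_mean_length(self):
        complete = _call(0, "annotated", length=10)
        partial = _call(1, "annotated", length=99)
        partial.complete = False
        partial.stop_position = None
        s = class_summary({"S1": [complete, partial]})
        assert s.union.loc["annotated", "n_tis"] == 2
        assert s.union.loc["annotated", "mean_orf_length_aa"] == 10


class TestSensitivity:
    def test_all_true_matrix_is_100_percent_everywhere(self):
        m = matrix_from_class_counts({"annotated": (3, 3), "lncRNA": (2, 2)}, n_samples=4)
        rep = sensitivity(m, scope="any_sample")
        assert (rep.table["sensitivity_pct"] == 100.0).all()

    def test_benchmark_class_counts_reproduce_published_percentages(self):
        counts = {
            "annotated": (70, 95),
            "out_of_frame": (3, 15),
            "upstream": (5, 8),
            "alternative": (4, 6),
            "lncRNA": (0, 5),
        }
        m = matrix_from_class_counts(counts, n_samples=6)
        rep = sensitivity(m, scope="any_sample")
        assert rep.table.loc["pooled", "n_detected"] == 82
        assert rep.table.loc["pooled", "n_total"] == 129
        assert rep.table.loc["pooled", "sensitivity_pct"] == 63.6
        assert rep.table.loc["annotated", "sensitivity_pct"] == 73.7
        assert rep.table.loc["out_of_frame", "sensitivity_pct"] == 20.0
        subset = sensitivity(
            m, scope="any_sample", class_filter=["annotated", "upstream", "alternative"]
        )
        assert subset.table.loc["pooled", "sensitivity_pct"] == 72.5

    def test_all_samples_scope_restricts_to_ubiquitous_orfs(self):
        m = matrix_from_class_counts(
            {"annotated": (34, 117)}, n_samples=6, detected_in="all"
        )
        rep = sensitivity(m, scope="all_samples")
        assert rep.table.loc["pooled", "sensitivity_pct"] == 29.1
        any_rep = sensitivity(m, scope="any_sample")
        assert (
            any_rep.table.loc["pooled", "sensitivity_pct"]
            >= rep.table.loc["pooled", "sensitivity_pct"]
        )


class TestHistogram:
    def test_all_false_matrix_lands_in_bin_zero(self):
        m = matrix_from_class_counts({"annotated": (0, 5)}, n_samples=6)
        hist = detection_histogram(m)
        assert hist[0] == 5 and hist.sum() == 5

    def test_histogram_matches_brute_force_row_sums(self):
        m = matrix_from_class_counts(
            {"annotated": (3, 5), "upstream": (1, 2)}, n_samples=4, detected_in="all"
        )
        hist = detection_histogram(m)
        rows = (m.detected & m.present).sum(axis=1)
        for k in hist.index:
            assert hist[k] == int((rows == k).sum())
        assert int(hist.sum()) == len(m.detected)


class TestStrata:
    def test_single_bin_when_all_genes_high_expression(self):
        m = matrix_from_class_counts({"annotated": (2, 3)}, n_samples=6)
        expr = {g: 50.0 for g in m.meta["gene_id"]}
        table, no_data = expression_strata(m, expr)
        assert set(table["expression_bin"]) == {">10"}
        assert no_data.empty

    def test_missing_expression_reported_separately(self):
        m = matrix_from_class_counts(
            {"annotated": (1, 2), "lncRNA": (0, 2)}, n_samples=6
        )
        expr = {g: 5.0 for g in m.meta.loc[m.meta.class_label == "annotated", "gene_id"]}
        table, no_data = expression_strata(m, expr)
        assert set(table["class_label"]) == {"annotated"}
        assert no_data.set_index("class_label").loc["lncRNA", "n_orfs"] == 2

    def test_strata_margins_equal_histogram_for_expressed_orfs(self):
        m = matrix_from_class_counts(
            {"annotated": (3, 6), "upstream": (2, 4)}, n_samples=5, detected_in="all"
        )
        rng = np.random.default_rng(0)
        expr = {g: float(10 ** rng.normal(0.5, 1)) for g in m.meta["gene_id"]}
        table, no_data = expression_strata(m, expr)
        assert no_data.empty
        hist = detection_histogram(m)
        margins = table.groupby("n_samples_detected")["n_orfs"].sum()
        for k, n in margins.items():
            assert n == hist[k]
        assert margins.sum() == hist.sum()
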