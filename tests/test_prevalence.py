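"""Prevalence tables, ratios and degrader summaries."""

import pandas as pd
import pytest

from conftest import truth_hits
from hmolocus.exceptions import ConsistencyError, UndefinedRatioError
from hmolocus.locus import classify_cohort
from hmolocus.prevalence import (
    degrader_summary,
    prevalence,
    prevalence_ratio,
)

FAMILIES = ["GH112", "GH136_I", "GH136_II", "GH10"]


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "family", "ref_id", "pct_identity"]
    )


def _sgb(pairs):
    return pd.DataFrame(pairs, columns=["genome_id", "sgb_id"])


class TestPrevalence:
    def test_no_hits_all_zero(self):
        sgb = _sgb([("g1", "S1"), ("g2", "S1")])
        table = prevalence(_hits([]), sgb, FAMILIES)
        frame = table.to_frame()
        assert (frame["global_count"] == 0).all()
        assert (frame["S1_count"] == 0).all()

    def test_paralogs_count_once(self):
        sgb = _sgb([("g1", "S1")])
        hits = _hits([("g1", f"gene{i}", "GH112", "r", 90.0) for i in range(3)])
        table = prevalence(hits, sgb, FAMILIES)
        assert table.count("GH112") == 1
        assert int(table.gene_counts.loc["g1", "GH112"]) == 3

    def test_unassigned_genome_raises(self):
        sgb = _sgb([("g1", "S1")])
        hits = _hits([("g2", "gene1", "GH112", "r", 90.0)])
        with pytest.raises(ConsistencyError, match="g2"):
            prevalence(hits, sgb, FAMILIES)

    def test_planted_cohort_matches_truth(self, small_cohort):
        _, _, sgb, truth = small_cohort
        table = prevalence(truth_hits(truth), sgb, FAMILIES)
        for family in FAMILIES:
            expected = sum(
                any(info["family"] == family for info in g.identities.values())
                for g in truth.genomes.values()
            )
            assert table.count(family) == expected

    def test_marginal_conservation(self, small_cohort):
        _, _, sgb, truth = small_cohort
        table = prevalence(truth_hits(truth), sgb, FAMILIES)
        for family in FAMILIES + ["GH136"]:
            per_sgb = sum(table.count(family, s) for s in sgb["sgb_id"].unique())
            assert per_sgb == table.count(family)

    def test_invariant_to_gene_order_and_strand(self, small_cohort):
        # prevalence depends only on the hit table, which carries no
        # coordinates; shuffling hit rows must not change any count
        _, _, sgb, truth = small_cohort
        hits = truth_hits(truth)
        shuffled = hits.sample(frac=1, random_state=7).reset_index(drop=True)
        a = prevalence(hits, sgb, FAMILIES).to_frame()
        b = prevalence(shuffled, sgb, FAMILIES).to_frame()
        pd.testing.assert_frame_equal(a, b)


class TestPrevalenceRatio:
    def test_reported_per_sgb_ratio_form(self):
        # 26 GH112 genomes vs 10 GH136 genomes in one SGB -> 2.6
        pairs = [(f"g{i}", "S1") for i in range(30)]
        rows = [(f"g{i}", "a", "GH112", "r", 90.0) for i in range(26)]
        rows += [(f"g{i}", "b", "GH136_I", "r", 90.0) for i in range(10)]
        table = prevalence(_hits(rows), _sgb(pairs), FAMILIES)
        assert prevalence_ratio(table, "GH112", "GH136", "S1") == pytest.approx(2.6)

    def test_equal_counts_ratio_one(self):
        pairs = [("g1", "S1"), ("g2", "S1")]
        rows = [("g1", "a", "GH112", "r", 90.0), ("g2", "b", "GH10", "r", 90.0)]
        table = prevalence(_hits(rows), _sgb(pairs), FAMILIES)
        assert prevalence_ratio(table, "GH112", "GH10") == 1.0

    def test_gh112_only_fraction_drives_ratio(self, references):
        # 30% of GH112 carriers lack GH136 -> GH112:GH136 = 1/0.7
        from hmolocus.synthetic import CohortDesign, simulate_cohort

        design = CohortDesign(
            n_sgbs=1,
            genomes_per_sgb=10,
            frac_gh112_only=0.3,
            frac_no_locus=0.0,
            seed=8,
        )
        _, sgb, truth = simulate_cohort(design, references)
        table = prevalence(truth_hits(truth), sgb, FAMILIES)
        assert prevalence_ratio(table, "GH112", "GH136") == pytest.approx(1 / 0.7)

    def test_zero_denominator_raises(self):
        table = prevalence(_hits([]), _sgb([("g1", "S1")]), FAMILIES)
        with pytest.raises(UndefinedRatioError, match="GH10"):
            prevalence_ratio(table, "GH112", "GH10")


class TestDegraderSummary:
    def test_all_primary_cohort(self):
        sgb = _sgb([("g1", "S1"), ("g2", "S1")])
        summary = degrader_summary({"g1": "primary", "g2": "primary"}, sgb)
        assert summary.loc["S1", "primary"] == 2
        assert summary.loc["S1", "secondary"] == 0
        assert summary.loc["S1", "none"] == 0

    def test_rows_sum_to_cohort_sizes(self, small_cohort):
        _, _, sgb, truth = small_cohort
        categories = classify_cohort(truth_hits(truth), sgb["genome_id"])
        summary = degrader_summary(categories, sgb)
        sizes = sgb.groupby("sgb_id").size()
        assert (summary.sum(axis=1) == sizes).all()

    def test_matches_truth_counts(self, small_cohort):
        _, _, sgb, truth = small_cohort
        categories = classify_cohort(truth_hits(truth), sgb["genome_id"])
        summary = degrader_summary(categories, sgb)
        expected = truth.category_counts()
        assert summary.sum(axis=0).to_dict() == expected

    def test_genomes_missing_from_categories_count_as_none(self):
        sgb = _sgb([("g1", "S1"), ("g2", "S2")])
        summary = degrader_summary({"g1": "primary"}, sgb)
        assert summary.loc["S2", "none"] == 1
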