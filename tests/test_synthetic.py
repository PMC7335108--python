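"""Synthetic cohort generator: identity control, category counts, determinism."""

import numpy as np
import pandas as pd
import pytest

from hmolocus.exceptions import InvalidInputError, InvalidParameterError
from hmolocus.homology import percent_identity
from hmolocus.synthetic import (
    AMINO_ACIDS,
    CohortDesign,
    TEMPLATE_GH136,
    _random_protein,
    default_references,
    expected_landscape,
    mutate_to_identity,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def gh112_ref(references):
    return next(r for r in references if r.ref_id == "GH112_L1-82").sequence


class TestMutateToIdentity:
    def test_identity_100_returns_reference(self, gh112_ref):
        assert mutate_to_identity(gh112_ref, 100, seed=5) == gh112_ref

    @pytest.mark.parametrize("target", [95, 85, 70, 60, 50])
    def test_hits_target_within_tolerance(self, gh112_ref, target):
        mutant = mutate_to_identity(gh112_ref, target, seed=7)
        assert percent_identity(gh112_ref, mutant) == pytest.approx(target, abs=3)

    def test_target_70_on_length_200_reference(self):
        reference = _random_protein(np.random.default_rng(1), 200)
        mutant = mutate_to_identity(reference, 70, seed=7)
        assert 67 <= percent_identity(reference, mutant) <= 73

    def test_deterministic_for_fixed_seed(self, gh112_ref):
        assert mutate_to_identity(gh112_ref, 70, seed=7) == mutate_to_identity(
            gh112_ref, 70, seed=7
        )

    def test_rejects_invalid_parameters(self, gh112_ref):
        with pytest.raises(InvalidParameterError):
            mutate_to_identity(gh112_ref, 0, seed=1)
        with pytest.raises(InvalidParameterError):
            mutate_to_identity(gh112_ref, 101, seed=1)
        with pytest.raises(InvalidInputError):
            mutate_to_identity("MKTAYIAK", 70, seed=1)  # < 20 residues


class TestCohortDesign:
    def test_fraction_invariant(self):
        with pytest.raises(InvalidParameterError):
            CohortDesign(frac_gh112_only=0.7, frac_no_locus=0.4).validate()

    def test_identity_range_invariant(self):
        with pytest.raises(InvalidParameterError):
            CohortDesign(identity_range=(90, 105)).validate()

    def test_template_must_contain_one_anchor(self):
        with pytest.raises(InvalidParameterError):
            CohortDesign(
                n_sgbs=1, locus_template_per_sgb=[("GH136_I", "GH136_II")]
            ).validate()
        with pytest.raises(InvalidParameterError):
            CohortDesign(
                n_sgbs=1, locus_template_per_sgb=[("GH112", "GH112")]
            ).validate()


class TestSimulateCohort:
    def test_exact_category_counts(self, references):
        design = CohortDesign(
            n_sgbs=2,
            genomes_per_sgb=10,
            frac_gh112_only=0.2,
            frac_no_locus=0.1,
            seed=3,
        )
        _, _, truth = simulate_cohort(design, references)
        assert truth.category_counts() == {"primary": 14, "secondary": 4, "none": 2}

    def test_empty_design(self, references):
        design = CohortDesign(n_sgbs=2, genomes_per_sgb=0, seed=1)
        genes, sgb, truth = simulate_cohort(design, references)
        assert genes.empty and sgb.empty and not truth.genomes

    def test_deterministic_byte_identical(self, references):
        design = CohortDesign(n_sgbs=1, genomes_per_sgb=6, seed=99)
        a = simulate_cohort(design, references)
        b = simulate_cohort(design, references)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].to_json() == b[2].to_json()

    def test_truth_consistent_with_planted_genes(self, small_cohort):
        _, genes, _, truth = small_cohort
        for g in truth.genomes.values():
            families = {info["family"] for info in g.identities.values()}
            if g.category == "primary":
                assert "GH112" in families and families & {"GH136_I", "GH136_II"}
            elif g.category == "secondary":
                assert "GH112" in families and not families & {"GH136_I", "GH136_II"}
            else:
                assert not g.identities and not g.planted_tokens

    def test_planted_identities_within_design_range(self, small_cohort):
        design, _, _, truth = small_cohort
        lo, hi = design.identity_range
        for g in truth.genomes.values():
            for info in g.identities.values():
                assert lo - 3 <= info["identity"] <= min(hi + 3, 100)

    def test_genes_non_overlapping_single_contig(self, small_cohort):
        _, genes, _, _ = small_cohort
        for _, table in genes.groupby("genome_id"):
            assert table["contig_id"].nunique() == 1
            ordered = table.sort_values("start")
            assert (ordered["start"] <= ordered["end"]).all()
            assert (
                ordered["start"].iloc[1:].to_numpy() > ordered["end"].iloc[:-1].to_numpy()
            ).all()

    def test_background_genes_below_40_percent_identity(self, references):
        """Uniform-random background proteins sit far below any homology
        threshold: max identity to any reference < 40% across 1000 genes."""
        rng = np.random.default_rng(12345)
        worst = 0.0
        for _ in range(1000):
            protein = _random_protein(rng, int(rng.integers(150, 401)))
            for ref in references:
                worst = max(worst, percent_identity(protein, ref.sequence))
        assert worst < 40.0


def test_expected_landscape_pads_with_hp():
    from hmolocus.synthetic import GenomeTruth

    truth = GenomeTruth(
        genome_id="g",
        sgb_id="s",
        category="primary",
        locus_strand="+",
        planted_tokens=list(TEMPLATE_GH136),
        anchor_gene_id="a",
        identities={},
        n_background_before=15,
        n_background_after=15,
    )
    window = expected_landscape(truth, n=11)
    anchor_at = window.index("GH112")
    assert anchor_at == 11
    assert len(window) == 23
    assert window[:4] == ["HP"] * 4  # 7 locus genes upstream + 4 HP padding
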