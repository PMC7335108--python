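"""OSA distance, PCoA ordination and representative selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

from _oracles import damerau_levenshtein, osa_recursive
from hmolocus.compare import (
    DistanceMatrix,
    distance_matrix,
    osa_distance,
    pcoa,
    read_distance_matrix,
    representative_landscape,
    write_distance_matrix,
)
from hmolocus.exceptions import InvalidInputError, InvalidParameterError
from hmolocus.landscape import Landscape

TOKENS = st.lists(st.sampled_from(["GH112", "GH136_I", "PP", "HP"]), max_size=8)


def _landscape(tokens, genome="G", anchor="a"):
    tokens = tuple(tokens)
    idx = tokens.index("GH112") if "GH112" in tokens else 0
    return Landscape(
        genome_id=genome,
        anchor_gene_id=anchor,
        tokens=tokens,
        anchor_index=idx,
        window=11,
        truncated_upstream=False,
        truncated_downstream=False,
    )


class TestOsaDistance:
    def test_identical_strings(self):
        assert osa_distance(["GH112", "PP"], ["GH112", "PP"]) == 0

    def test_adjacent_transposition_costs_one(self):
        assert osa_distance(["GH136_I", "GH136_II"], ["GH136_II", "GH136_I"]) == 1

    def test_osa_exceeds_unrestricted_damerau_levenshtein(self):
        # the classic restriction case: CA -> ABC
        ca, abc = ["C", "A"], ["A", "B", "C"]
        assert osa_distance(ca, abc) == 3
        assert damerau_levenshtein(ca, abc) == 2

    @given(TOKENS, TOKENS)
    def test_matches_recursive_oracle(self, s, t):
        assert osa_distance(s, t) == osa_recursive(s, t)

    @given(TOKENS, TOKENS)
    def test_metric_like_properties(self, s, t):
        d = osa_distance(s, t)
        assert d == osa_distance(t, s)
        assert d >= abs(len(s) - len(t))
        assert d <= max(len(s), len(t))
        assert (d == 0) == (list(s) == list(t))


class TestDistanceMatrix:
    def test_identical_landscapes_zero_matrix(self):
        landscapes = [_landscape(["GH112", "PP"], anchor=f"a{i}") for i in range(3)]
        dm = distance_matrix(landscapes)
        assert (dm.values == 0).all()

    def test_one_deletion_off_diagonal_one(self):
        a = _landscape(["GH112", "PP", "HP"], anchor="a1")
        b = _landscape(["GH112", "PP"], anchor="a2")
        dm = distance_matrix([a, b])
        assert dm.values[0, 1] == 1

    def test_symmetry_and_zero_diagonal(self, small_cohort):
        rng = np.random.default_rng(0)
        vocab = ["GH112", "GH136_I", "PP", "SBP", "HP", "OTHER"]
        landscapes = [
            _landscape(rng.choice(vocab, size=rng.integers(1, 12)), anchor=f"a{i}")
            for i in range(12)
        ]
        dm = distance_matrix(landscapes)
        assert (dm.values == dm.values.T).all()
        assert (np.diag(dm.values) == 0).all()

    def test_exclude_other_drops_tokens(self):
        a = _landscape(["GH112", "OTHER", "PP"], anchor="a1")
        b = _landscape(["GH112", "PP"], anchor="a2")
        assert distance_matrix([a, b], include_other=False).values[0, 1] == 0
        assert distance_matrix([a, b], include_other=True).values[0, 1] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            distance_matrix([])

    def test_tsv_round_trip(self, tmp_path):
        a = _landscape(["GH112", "PP", "HP"], anchor="a1")
        b = _landscape(["GH112", "PP"], anchor="a2")
        dm = distance_matrix([a, b])
        write_distance_matrix(dm, tmp_path / "d.tsv")
        back = read_distance_matrix(tmp_path / "d.tsv")
        assert back.ids == dm.ids
        assert (back.values == dm.values).all()


class TestPcoa:
    def test_all_zero_distances(self):
        dm = DistanceMatrix(ids=["a", "b", "c"], values=np.zeros((3, 3), dtype=int))
        ordination = pcoa(dm, k=2)
        assert np.allclose(ordination.coordinates, 0)
        assert np.allclose(ordination.eigenvalues, 0)

    def test_two_points_axis1_separation_is_d(self):
        d = 7
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0, d], [d, 0]]))
        ordination = pcoa(dm, k=1)
        gap = abs(ordination.coordinates[0, 0] - ordination.coordinates[1, 0])
        assert gap == pytest.approx(d, abs=1e-10)

    def test_unit_square_reconstruction(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dist = squareform(pdist(pts))
        dm = DistanceMatrix(ids=list("abcd"), values=dist)
        ordination = pcoa(dm, k=2)
        recon = squareform(pdist(ordination.coordinates))
        assert np.allclose(recon, dist, atol=1e-8)

    def test_matches_scikit_bio(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 3))
        dist = squareform(pdist(pts))
        dm = DistanceMatrix(ids=[f"p{i}" for i in range(15)], values=dist)
        ours = pcoa(dm, k=3)
        theirs = skbio_pcoa(dist, number_of_dimensions=3)
        assert np.allclose(
            np.sort(ours.eigenvalues[:3]), np.sort(theirs.eigvals.to_numpy()[:3]), atol=1e-8
        )
        assert np.allclose(
            np.abs(ours.coordinates), np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-6
        )

    def test_negative_eigenvalues_reported_for_osa(self):
        # OSA violates the triangle inequality, so classical scaling on the
        # restriction case produces negative eigenvalues
        landscapes = [
            _landscape(["C", "A"], anchor="a1"),
            _landscape(["A", "C"], anchor="a2"),
            _landscape(["A", "B", "C"], anchor="a3"),
        ]
        dm = distance_matrix(landscapes)
        ordination = pcoa(dm, k=2)
        assert (ordination.eigenvalues >= 0).all()
        assert len(ordination.negative_eigenvalues) >= 1

    def test_k_must_be_less_than_n(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2), dtype=int))
        with pytest.raises(InvalidParameterError):
            pcoa(dm, k=2)


class TestRepresentativeLandscape:
    def test_majority_string_wins(self):
        group = [_landscape(["GH112", "PP"], anchor=f"a{i}") for i in range(3)]
        group.append(_landscape(["GH112", "HP", "HP"], anchor="a3"))
        assert representative_landscape(group).tokens == ("GH112", "PP")

    def test_tie_broken_by_mean_distance(self):
        # all distinct; the central string is 1 edit from the others
        group = [
            _landscape(["GH112", "PP", "HP"], anchor="a0"),  # central
            _landscape(["GH112", "PP"], anchor="a1"),
            _landscape(["GH112", "PP", "HP", "HP"], anchor="a2"),
            _landscape(["GH112", "SBP", "HP"], anchor="a3"),
        ]
        assert representative_landscape(group).anchor_gene_id == "a0"

    def test_tie_on_mean_distance_broken_lexicographically(self):
        group = [
            _landscape(["GH112", "AAA"], anchor="a0"),
            _landscape(["GH112", "AAA"], anchor="a1"),
            _landscape(["GH112", "ZZZ"], anchor="a2"),
            _landscape(["GH112", "ZZZ"], anchor="a3"),
        ]
        assert representative_landscape(group).tokens == ("GH112", "AAA")

    def test_output_is_group_member(self):
        rng = np.random.default_rng(5)
        vocab = ["GH112", "PP", "HP"]
        group = [
            _landscape(rng.choice(vocab, size=rng.integers(1, 6)), anchor=f"a{i}")
            for i in range(9)
        ]
        rep = representative_landscape(group)
        assert any(rep is member for member in group)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            representative_landscape([])
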