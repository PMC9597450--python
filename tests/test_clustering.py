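"""Dice similarity, UPGMA against reference linkage, PCoA geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial import procrustes
from scipy.spatial.distance import dice as scipy_dice_dissimilarity
from scipy.spatial.distance import squareform

from sesamediv.band_matrix import BandMatrix, BandRecord
from sesamediv.clustering import (
    SimilarityMatrix,
    combined_feature_matrix,
    dice_similarity,
    dice_similarity_matrix,
    distance_from_similarity,
    pcoa,
    upgma,
)
from sesamediv.errors import UndefinedStatisticError, ValidationError


def _dist_frame(d, labels=None):
    labels = labels or [f"L{i}" for i in range(len(d))]
    return pd.DataFrame(np.asarray(d, dtype=float), index=labels, columns=labels)


class TestDice:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 1, 0, 1), (1, 1, 0, 1), 1.0),
            ((1, 1, 0), (0, 0, 1), 0.0),
            ((1, 1, 0), (1, 0, 1), 0.5),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert dice_similarity(x, y) == pytest.approx(expected)

    def test_symmetry_and_identity_only_for_equal_profiles(self, rng):
        for _ in range(20):
            x, y = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
            if not (x.any() or y.any()):
                continue
            assert dice_similarity(x, y) == pytest.approx(dice_similarity(y, x))
            if dice_similarity(x, y) == 1.0:
                assert (x == y).all()

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            x, y = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
            if not (x.any() and y.any()):
                continue
            assert dice_similarity(x, y) == pytest.approx(
                1.0 - scipy_dice_dissimilarity(x.astype(bool), y.astype(bool))
            )

    def test_all_zero_pair_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dice_similarity((0, 0), (0, 0))

    def test_matrix_validation(self):
        with pytest.raises(ValidationError):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))


class TestUpgma:
    def test_two_leaf_cherry(self):
        tree = upgma(_dist_frame([[0, 0.4], [0.4, 0]], ["A", "B"]))
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.labels) == ["A", "B"]
        assert tree.newick() == "(A:0.2,B:0.2);"

    def test_three_leaf_hand_agglomeration(self):
        d = _dist_frame([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]], list("ABC"))
        tree = upgma(d)
        assert tree.newick() == "((A:0.1,B:0.1):0.2,C:0.3);"
        coph = tree.cophenetic()
        assert coph.loc["A", "B"] == pytest.approx(0.2)
        assert coph.loc["A", "C"] == pytest.approx(0.6)

    def test_matches_reference_linkage_on_random_matrices(self, rng):
        """Cophenetic distances equal scipy average-linkage on 50 random cases."""
        for _ in range(50):
            pts = rng.random((6, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            df = _dist_frame(d)
            coph = upgma(df).cophenetic()
            ref = pd.DataFrame(
                squareform(cophenet(linkage(squareform(d), method="average"))),
                index=df.index,
                columns=df.columns,
            )
            assert np.allclose(
                coph.values, ref.loc[coph.index, coph.columns].values, atol=1e-12
            )

    def test_reconstructs_ultrametric_input_exactly(self):
        """UPGMA on cophenetic distances of a tree recovers that tree."""
        d = _dist_frame(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ],
            list("ABCD"),
        )
        tree = upgma(d)
        assert np.allclose(tree.cophenetic().values, d.loc[tree.cophenetic().index, tree.cophenetic().columns].values)
        assert tree.newick() == "((A:0.1,B:0.1):0.3,(C:0.2,D:0.2):0.2);"

    def test_ultrametric_property(self, rng):
        """All leaves are equidistant from the root."""
        d = rng.random((7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(_dist_frame(d))

        def depths(node, acc=0.0):
            if node.is_leaf:
                return [acc]
            out = []
            for ch in node.children:
                out.extend(depths(ch, acc + (node.height - ch.height)))
            return out

        dep = depths(tree.root)
        assert max(dep) - min(dep) < 1e-12

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValidationError):
            upgma(_dist_frame([[0, 1], [2, 0]]))


class TestPcoa:
    def test_two_points(self):
        o = pcoa(_dist_frame([[0, 1], [1, 0]]))
        assert o.coordinates.shape[1] == 1
        assert sorted(o.coordinates[:, 0]) == pytest.approx([-0.5, 0.5])
        assert o.explained_percent[0] == pytest.approx(100.0)

    def test_three_equidistant_points_split_variance(self):
        o = pcoa(_dist_frame([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        assert len(o.explained_percent) == 2
        assert o.explained_percent[0] == pytest.approx(o.explained_percent[1])

    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((9, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        o = pcoa(_dist_frame(d))
        _, _, disparity = procrustes(pts, o.coordinates[:, :2])
        assert disparity < 1e-8

    def test_agrees_with_skbio_reference(self, rng):
        """Explained variance matches scikit-bio's PCoA on the same matrix."""
        import skbio

        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(7)]
        o = pcoa(pd.DataFrame(d, index=labels, columns=labels))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids=labels))
        n_axes = len(o.explained_percent)
        assert np.allclose(
            o.explained_percent,
            100 * ref.proportion_explained.values[:n_axes],
            atol=1e-8,
        )
        for ax in range(2):
            assert np.allclose(
                np.abs(o.coordinates[:, ax]),
                np.abs(ref.samples.values[:, ax]),
                atol=1e-8,
            )

    def test_explained_percentages_sorted_and_positive(self, rng):
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        o = pcoa(_dist_frame(d))
        ev = o.explained_percent
        assert (ev >= 0).all() and (np.diff(ev) <= 1e-12).all()
        assert ev.sum() == pytest.approx(100.0)


class TestCombinedFeatures:
    def _matrix(self, patterns, genotypes, assay="A"):
        recs = [
            BandRecord(assay_id=assay, band_id=f"b{i}", fragment_size=900 - i, presence=tuple(p))
            for i, p in enumerate(patterns)
        ]
        return BandMatrix(list(genotypes), recs)

    def test_markers_only_is_transposed_binary_matrix(self, six_genotypes):
        m = self._matrix([(1, 0, 1, 0, 1, 0), (0, 1, 0, 1, 0, 1)], six_genotypes)
        feat = combined_feature_matrix([m])
        assert feat.shape == (6, 2)
        assert np.array_equal(feat.values, m.profiles().values.astype(float))

    def test_constant_karyotype_column_dropped_with_warning(self, six_genotypes):
        m = self._matrix([(1, 0, 1, 0, 1, 0)], six_genotypes)
        karyo = pd.DataFrame(
            {"TF_percent": np.linspace(40, 45, 6), "const": 7.0},
            index=six_genotypes,
        )
        with pytest.warns(UserWarning, match="const"):
            feat = combined_feature_matrix([m], karyo)
        assert "karyo|const" not in feat.columns
        z = feat["karyo|TF_percent"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_column_bookkeeping(self, six_genotypes):
        m1 = self._matrix([(1, 0, 1, 0, 1, 0)] * 3, six_genotypes, assay="A")
        m2 = self._matrix([(0, 1, 1, 0, 0, 1)] * 2, six_genotypes, assay="B")
        karyo = pd.DataFrame(
            {"x": np.arange(6.0), "y": np.arange(6.0) ** 2}, index=six_genotypes
        )
        feat = combined_feature_matrix([m1, m2], karyo)
        assert feat.shape[1] == 3 + 2 + 2

    def test_roster_mismatch_raises(self, six_genotypes):
        m1 = self._matrix([(1, 0, 1, 0, 1, 0)], six_genotypes)
        m2 = self._matrix([(1, 0, 1)], ["a", "b", "c"])
        with pytest.raises(ValidationError, match="roster"):
            combined_feature_matrix([m1, m2])
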