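"""Dice similarity, UPGMA dendrograms, principal coordinates and the
combined cyto-molecular feature matrix.

The similarity between two binary band profiles is the Dice coefficient
``2a / (2a + b + c)`` (a = shared presences, b/c = presences private to
either profile); clustering operates on the complementary distance
``1 - similarity``.  UPGMA is the classical unweighted pair-group method:
at every step the two clusters at minimal average distance are merged and
the new node is placed at half that distance, producing an ultrametric
tree.  Ties are broken deterministically in favour of the pair whose
smallest member label sorts first.  Principal coordinates (classical
metric MDS) embeds the distance matrix by eigendecomposition of the
double-centred matrix ``-D²/2``; negative eigenvalues are clamped to zero
and excluded from the explained-variance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_matrix import BandMatrix
from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "SimilarityMatrix",
    "TreeNode",
    "Dendrogram",
    "Ordination",
    "dice_similarity",
    "dice_similarity_matrix",
    "distance_from_similarity",
    "upgma",
    "pcoa",
    "combined_feature_matrix",
]


def dice_similarity(x, y) -> float:
    """Dice coefficient ``2a / (2a + b + c)`` of two equal-length 0/1 profiles."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValidationError("profiles differ in length")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if 2 * a + b + c == 0:
        raise UndefinedStatisticError(
            "Dice similarity undefined for two all-zero profiles"
        )
    return 2.0 * a / (2.0 * a + b + c)


@dataclass
class SimilarityMatrix:
    """Square symmetric Dice-similarity matrix with its label order."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("similarity matrix shape/label mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def dice_similarity_matrix(matrix: BandMatrix) -> SimilarityMatrix:
    """All pairwise Dice similarities between genotype band profiles."""
    profiles = matrix.profiles().to_numpy()
    n = len(matrix.genotypes)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = dice_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(list(matrix.genotypes), sim)


def distance_from_similarity(sim: SimilarityMatrix) -> pd.DataFrame:
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sim.labels, columns=sim.labels)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; height is distance-from-leaves."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def newick(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            core = self.label
        else:
            core = "(" + ",".join(ch.newick(self.height) for ch in self.children) + ")"
        if parent_height is None:
            return core + ";"
        return f"{core}:{parent_height - self.height:.10g}"


@dataclass
class Dendrogram:
    """Rooted ultrametric binary tree from UPGMA agglomeration."""

    root: TreeNode

    @property
    def labels(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x height of the join node)."""
        labels = sorted(self.labels)
        d = pd.DataFrame(0.0, index=labels, columns=labels)

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            groups = [visit(ch) for ch in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a in groups[i]:
                        for b in groups[j]:
                            d.loc[a, b] = d.loc[b, a] = 2.0 * node.height
            return [leaf for g in groups for leaf in g]

        visit(self.root)
        return d


def _check_distance(d: pd.DataFrame) -> None:
    v = d.to_numpy(dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(v, v.T):
        raise ValidationError("distance matrix not symmetric")
    if not np.allclose(np.diag(v), 0.0):
        raise ValidationError("distance diagonal must be 0")


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a labelled distance matrix.

    Average linkage weighted by cluster sizes (the unweighted pair-group
    method); node height is half the merge distance; ties broken by the
    lexicographically smallest member label of the candidate pair.
    """
    _check_distance(distance)
    labels = [str(c) for c in distance.columns]
    if len(labels) < 2:
        raise ValidationError("UPGMA needs >= 2 leaves")
    d = {
        frozenset((a, b)): float(distance.iloc[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    clusters: dict[str, TreeNode] = {
        lab: TreeNode(height=0.0, label=lab) for lab in labels
    }
    sizes = {lab: 1 for lab in labels}
    # cluster key = lexicographically smallest member label
    while len(clusters) > 1:
        best = None
        for key, dist in d.items():
            a, b = sorted(key)
            cand = (dist, a, b)
            if best is None or cand < best:
                best = cand
        dist, a, b = best
        merged = TreeNode(height=dist / 2.0, children=[clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        others = [k for k in clusters if k not in (a, b)]
        for o in others:
            dao = d.pop(frozenset((a, o)))
            dbo = d.pop(frozenset((b, o)))
            # size-weighted average = mean over all original leaf pairs,
            # which is what the *unweighted* pair-group method computes
            d[frozenset((min(a, b), o))] = (na * dao + nb * dbo) / (na + nb)
        del d[frozenset((a, b))]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        key = min(a, b)
        clusters[key] = merged
        sizes[key] = na + nb
    return Dendrogram(root=next(iter(clusters.values())))


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """PCoA scores and explained-variance percentages per axis."""

    labels: list[str]
    coordinates: np.ndarray  # samples x axes
    explained_percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(distance: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """Classical principal-coordinates analysis of a distance matrix.

    Gower double-centring of ``-D**2 / 2`` followed by symmetric
    eigendecomposition; axes are eigenvectors scaled by the square root of
    their (positive) eigenvalues, ordered by decreasing eigenvalue.
    """
    _check_distance(distance)
    labels = [str(c) for c in distance.columns]
    n = len(labels)
    if n < 2:
        raise ValidationError("PCoA needs >= 2 samples")
    dsq = distance.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ dsq @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval).max())
    eigval_pos = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(eigval_pos)
    explained = 100.0 * eigval_pos / eigval_pos.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        explained = explained[:n_axes]
    return Ordination(labels=labels, coordinates=coords, explained_percent=explained)


# ---------------------------------------------------------------------------
# Combined cyto-molecular feature matrix
# ---------------------------------------------------------------------------


def combined_feature_matrix(
    band_matrices: list[BandMatrix],
    karyotype_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genotypes x features matrix joining binary bands with z-scored
    karyotype indices.

    Band columns keep their 0/1 coding; numeric karyotype columns are
    standardised to zero mean and unit (sample) variance.  Constant
    karyotype columns carry no information and are dropped with a warning.
    Rosters must agree across inputs.
    """
    import warnings

    if not band_matrices:
        raise ValidationError("need at least one band matrix")
    roster = list(band_matrices[0].genotypes)
    blocks = []
    for bm in band_matrices:
        if list(bm.genotypes) != roster:
            missing = sorted(set(roster) ^ set(bm.genotypes))
            raise ValidationError(
                f"genotype roster mismatch between band matrices: {missing}"
            )
        prof = bm.profiles()
        prof.columns = [f"{a}|{b}" for a, b in prof.columns]
        blocks.append(prof.astype(float))
    if karyotype_table is not None:
        num = karyotype_table.select_dtypes("number")
        missing = sorted(set(roster) - set(num.index.astype(str)))
        if missing:
            raise ValidationError(f"karyotype table lacks genotypes: {missing}")
        num = num.loc[roster]
        keep = {}
        for col in num.columns:
            sd = num[col].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                warnings.warn(
                    f"dropping constant karyotype column {col!r}", stacklevel=2
                )
                continue
            keep[f"karyo|{col}"] = (num[col] - num[col].mean()) / sd
        if keep:
            blocks.append(pd.DataFrame(keep, index=roster))
    out = pd.concat(blocks, axis=1)
    out.index.name = "genotype"
    return out
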