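"""Dice similarity, UPGMA dendrograms and principal coordinates.

Computes, per marker system and for the pooled cyto-molecular data, the
Dice genetic-similarity matrix among the six genotypes, the UPGMA tree
(newick) and a principal-coordinates ordination, plus the combined
marker + karyotype feature matrix ordered by the UPGMA leaf order for
heatmap rendering.

Reads results/data/ and results/karyotype/, writes results/clustering/.
"""

from pathlib import Path

import pandas as pd

from sesamediv.band_matrix import BandMatrix, read_band_matrix
from sesamediv.clustering import (
    combined_feature_matrix,
    dice_similarity_matrix,
    distance_from_similarity,
    pcoa,
    upgma,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "clustering"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = {
        name: read_band_matrix(ROOT / "data" / f"bands_{name}.tsv")
        for name in ("issr", "scot", "sds")
    }
    pooled = BandMatrix(
        list(matrices["issr"].genotypes),
        [r for m in matrices.values() for r in m.records],
    )
    matrices["all_markers"] = pooled
    for name, m in matrices.items():
        sim = dice_similarity_matrix(m)
        sim.to_frame().round(4).to_csv(OUT / f"similarity_{name}.tsv", sep="\t")
        dist = distance_from_similarity(sim)
        tree = upgma(dist)
        (OUT / f"upgma_{name}.nwk").write_text(tree.newick() + "\n")
        ordn = pcoa(dist)
        scores = ordn.to_frame()
        scores.loc["explained_percent"] = ordn.explained_percent
        scores.round(4).to_csv(OUT / f"pcoa_{name}.tsv", sep="\t")
        ev = ordn.explained_percent
        print(
            f"{name}: UPGMA leaf order {tree.leaf_order()}; "
            f"PCo1/PCo2 explain {ev[0]:.1f}% / {ev[1]:.1f}%"
        )
    karyo = pd.read_csv(ROOT / "karyotype" / "karyotype_summary.tsv", sep="\t", index_col=0)
    karyo.index = list(matrices["issr"].genotypes)  # G1..G6 -> accession names
    features = combined_feature_matrix(list(matrices.values())[:3], karyo)
    order = upgma(
        distance_from_similarity(dice_similarity_matrix(pooled))
    ).leaf_order()
    features.loc[order].to_csv(OUT / "combined_features.tsv", sep="\t")
    print(f"combined feature matrix: {features.shape[0]} genotypes x {features.shape[1]} features")
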