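"""Karyotype asymmetry indices, formulas and ideograms per genotype.

The synthetic chromosome sets were built to the published haploid length,
pooled short-arm fraction (TF%) and chromosome-length CV of each genotype,
so HCL, TF%, AsK%, CVcl and A2 reproduce the published values exactly;
centromere-position spread (CVci, AI, S%, Stebbins letter) is not
constrained by the construction and differs.

Reads results/data/karyotypes.tsv, writes results/karyotype/.
"""

from pathlib import Path

from sesamediv.karyotype import (
    ideogram_svg,
    ideogram_table,
    read_karyotypes,
    summary_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "karyotype"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    ksets = read_karyotypes(ROOT / "data" / "karyotypes.tsv")
    table = summary_table(ksets)
    table.to_csv(OUT / "karyotype_summary.tsv", sep="\t")
    for ks in ksets:
        ideogram_table(ks).to_csv(OUT / f"ideogram_{ks.genotype}.tsv", sep="\t")
        (OUT / f"ideogram_{ks.genotype}.svg").write_text(ideogram_svg(ks))
    cols = ["HCL_um", "TF_percent", "AsK_percent", "A", "MCA", "CVcl", "A2", "Stebbins", "KF"]
    print(table[cols].to_string())
    print(
        "\ninvariant check: TF% + AsK% =",
        sorted((table["TF_percent"] + table["AsK_percent"]).round(6).unique()),
    )
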