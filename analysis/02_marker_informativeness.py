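"""Band accounting and marker-informativeness tables for ISSR and SCoT.

Reproduces the published per-primer structure: P%, PIC (banding-phenotype
mode), EMR, MI and Rp per primer, with Total (pooled P%) and Average
(mean P%) rows.  Also writes the per-genotype unique-band catalogue and
the per-genotype SDS-PAGE accounting.

Reads results/data/, writes results/markers/.
"""

from pathlib import Path

from sesamediv.band_matrix import (
    read_band_matrix,
    summarize_genotype,
    unique_band_catalogue,
)
from sesamediv.informativeness import informativeness_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "markers"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("issr", "scot"):
        m = read_band_matrix(ROOT / "data" / f"bands_{name}.tsv")
        table = informativeness_table(m)
        table.to_csv(OUT / f"informativeness_{name}.tsv", sep="\t")
        uniq = unique_band_catalogue(m)
        uniq.to_csv(OUT / f"unique_bands_{name}.tsv", sep="\t")
        print(
            f"{name.upper()}: {int(table.loc['Total', 'TAB'])} bands over "
            f"{len(table) - 2} primers; mean P% = "
            f"{table.loc['Average', 'P_percent']:.2f}, pooled P% = "
            f"{table.loc['Total', 'P_percent']:.2f}; "
            f"{int(uniq['n_total'].sum())} unique bands"
        )
    sds = read_band_matrix(ROOT / "data" / "bands_sds.tsv", unit="kDa")
    rows = []
    for g in sds.genotypes:
        acc = summarize_genotype(sds, g)
        acc["P_percent"] = round(100.0 * acc["PB"] / acc["TAB"], 2)
        rows.append({"genotype": g, **acc})
    import pandas as pd

    sds_table = pd.DataFrame(rows).set_index("genotype")
    sds_table.to_csv(OUT / "sds_page_accounting.tsv", sep="\t")
    print("SDS-PAGE per-genotype accounting:")
    print(sds_table.to_string())
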