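"""Dominant-marker population genetics on the replicate individuals.

Treats each genotype's replicate individuals as one population and
computes the Hardy-Weinberg dominant-marker statistics (Na, Ne, Shannon I,
He, uHe, %P) per population for each marker system, mirroring the
published per-genotype diversity table structurally.  Absolute values
depend on the synthetic replicate count and flip rate, which the study
does not report, so only the structure and invariants are comparable.

Reads results/data/, writes results/popgen/.
"""

from pathlib import Path

import pandas as pd

from sesamediv.band_matrix import read_band_matrix
from sesamediv.popgen import popgen_summary, populations_from_map

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "popgen"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    pmap = pd.read_csv(ROOT / "data" / "population_map.tsv", sep="\t")
    pops = populations_from_map(pmap)
    for name in ("issr", "scot"):
        m = read_band_matrix(ROOT / "data" / f"bands_{name}_individuals.tsv")
        df = popgen_summary(m, pops)
        df.to_csv(OUT / f"popgen_{name}.tsv", sep="\t")
        print(f"{name.upper()} ({len(m.records)} loci, N = {pops[0].size}/population):")
        print(df.to_string())
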