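"""Generate the synthetic study inputs from the published summary tables.

The raw gels and chromosome slides behind the study were never deposited,
so every downstream analysis runs on synthetic data constructed to match
the published per-primer band accounting (ISSR, SCoT), the SDS-PAGE band
structure, and the per-genotype karyotype constraints (haploid length,
short-arm fraction, chromosome-length CV).  Ten replicate individuals per
genotype with a 10% band-flip rate provide the within-genotype variation
the population-genetic statistics require.

Writes results/data/: band matrices, individual-level matrices, the
population map and the karyotype measurement table.
"""

from pathlib import Path

from sesamediv.study import simulate_study_data, write_study_data

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20260925

if __name__ == "__main__":
    data = simulate_study_data(seed=SEED)
    manifest = write_study_data(data, OUT)
    print(f"seed {SEED}: wrote {len(manifest['files'])} files to {OUT}")
    print(
        f"ISSR: {len(data.issr.records)} bands, "
        f"SCoT: {len(data.scot.records)} bands, "
        f"SDS-PAGE: {len(data.sds.records)} bands, "
        f"{data.issr_individuals.n_genotypes} individuals "
        f"across {len(set(data.population_map['population']))} genotypes"
    )
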