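"""Published summary tables used as inputs to the synthetic generators.

The study released per-primer band accounting (monomorphic / unique /
polymorphic / total counts and fragment-size spans for 20 ISSR and 25 SCoT
primers), a per-genotype SDS-PAGE band accounting, and per-genotype
karyotype parameters — but not the underlying raw band matrices or
chromosome measurements.  These printed summaries are embedded here as
small inline tables; the generators in :mod:`sesamediv.synthetic` construct
data that reproduces them where the statistic is a function of the counts.

The SDS-PAGE profile is an explicit synthetic reconstruction: an 8-band,
6-genotype matrix consistent with every published constraint (four bands
monomorphic, the 2 and 59 kDa bands carried only by G4 and G5, no unique
bands, per-genotype totals 5/5/6/7/7/6).
"""

from __future__ import annotations

import io
import math

import pandas as pd

from .band_matrix import BandMatrix, BandRecord
from .synthetic import AssaySpec

__all__ = [
    "issr_primer_counts",
    "scot_primer_counts",
    "sds_page_matrix",
    "karyotype_constraints",
    "assay_specs_from_counts",
    "GENOTYPES",
]

#: The six sesame genotypes (landrace accessions) of the study.
GENOTYPES = ["Ahs-670", "As-1236", "Bah-697", "Jiz-511", "Jiz-517", "Bah-312"]

_ISSR_TSV = """\
assay_id\tMB\tUB\tPB\tTAB\tfs_larger\tfs_smaller
ISSR 1\t6\t3\t8\t14\t960\t180
ISSR 2\t0\t9\t19\t19\t1140\t75
ISSR 3\t2\t0\t4\t6\t950\t445
ISSR 4\t5\t0\t1\t6\t980\t275
ISSR 5\t1\t6\t12\t13\t1260\t370
ISSR 6\t1\t8\t13\t14\t1280\t240
ISSR 7\t4\t3\t9\t13\t1330\t410
ISSR 8\t5\t2\t6\t11\t1070\t290
ISSR 9\t0\t3\t7\t7\t1540\t330
ISSR 10\t0\t6\t17\t17\t1245\t160
ISSR 11\t7\t2\t2\t9\t1425\t260
ISSR 12\t10\t2\t4\t14\t1330\t215
ISSR 13\t4\t3\t10\t14\t1370\t190
ISSR 14\t2\t4\t11\t13\t1280\t290
ISSR 15\t1\t3\t12\t13\t1040\t210
ISSR 16\t6\t0\t4\t10\t1400\t125
ISSR 17\t6\t0\t3\t9\t980\t230
ISSR 18\t3\t4\t7\t10\t380\t95
ISSR 19\t4\t2\t6\t10\t1110\t240
ISSR 20\t5\t2\t6\t11\t1065\t280
"""

_SCOT_TSV = """\
assay_id\tMB\tUB\tPB\tTAB\tfs_larger\tfs_smaller
SCoT 1\t4\t1\t5\t9\t885\t260
SCoT 2\t2\t0\t8\t10\t1480\t285
SCoT 3\t4\t0\t2\t6\t480\t150
SCoT 4\t0\t5\t13\t13\t1700\t445
SCoT 5\t6\t0\t3\t9\t1520\t350
SCoT 6\t1\t6\t7\t8\t2150\t500
SCoT 7\t8\t1\t5\t13\t1430\t330
SCoT 8\t2\t2\t7\t9\t530\t350
SCoT 9\t4\t1\t5\t9\t1250\t470
SCoT 10\t1\t2\t4\t5\t1580\t830
SCoT 11\t2\t5\t8\t10\t1210\t350
SCoT 12\t0\t1\t12\t12\t1370\t200
SCoT 13\t2\t2\t6\t8\t1530\t340
SCoT 14\t0\t4\t10\t10\t950\t280
SCoT 15\t1\t2\t8\t9\t2040\t510
SCoT 16\t6\t1\t4\t10\t380\t80
SCoT 17\t2\t1\t7\t9\t1490\t310
SCoT 18\t2\t0\t4\t6\t200\t100
SCoT 19\t2\t1\t9\t11\t270\t100
SCoT 20\t2\t2\t9\t11\t330\t100
SCoT 21\t0\t18\t31\t31\t1940\t90
SCoT 22\t5\t5\t9\t14\t1400\t200
SCoT 23\t1\t3\t13\t14\t930\t110
SCoT 24\t4\t2\t7\t11\t420\t170
SCoT 25\t0\t11\t18\t18\t1300\t155
"""

# Per-genotype karyotype parameters: the constraints the karyotype
# generator targets (HCL, TF%, CVcl) plus the remaining published columns
# kept for reference/reporting.
_KARYO_TSV = """\
genotype\tn2\thcl_um\ttf_percent\task_percent\ts_percent\tci\ta\tmca\tcv_cl\tcv_ci\tai\tstebbins\ta1\ta2\tkf
G1\t26\t108.47\t41.50\t58.50\t43.24\t0.42\t0.17\t16.83\t21.54\t14.92\t144.33\t2B\t0.27\t0.22\t2 nsm (−)+12 nst+12 nm
G2\t26\t127.33\t43.82\t56.18\t28.06\t0.43\t0.13\t12.86\t26.19\t9.60\t272.83\t2B\t0.22\t0.26\t2 nsm (−)+8 nst+14 nm
G3\t26\t88.76\t43.77\t56.23\t34.95\t0.43\t0.13\t13.03\t22.55\t6.54\t344.63\t2B\t0.22\t0.23\t4 nsm (−)+10 nst+12 nm
G4\t26\t103.85\t42.25\t57.75\t40.68\t0.43\t0.15\t15.07\t25.17\t10.76\t233.96\t1B\t0.25\t0.25\t6 nsm (−)+8 nst+10 nm
G5\t26\t115.40\t43.47\t56.53\t51.28\t0.43\t0.14\t13.56\t17.56\t12.62\t139.22\t2A\t0.22\t0.18\t4 nsm (−)+10 nst+12 nm
G6\t26\t119.09\t44.06\t55.94\t41.43\t0.44\t0.12\t12.11\t21.24\t13.50\t157.36\t2B\t0.20\t0.21\t8 nsm (−)+10 nst+8 nm
"""


def _read(tsv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(tsv), sep="\t")


def issr_primer_counts() -> pd.DataFrame:
    """Per-primer band accounting for the 20 ISSR primers."""
    return _read(_ISSR_TSV).set_index("assay_id")


def scot_primer_counts() -> pd.DataFrame:
    """Per-primer band accounting for the 25 SCoT primers."""
    return _read(_SCOT_TSV).set_index("assay_id")


def karyotype_constraints() -> pd.DataFrame:
    """Published per-genotype karyotype parameters (generator targets)."""
    return _read(_KARYO_TSV).set_index("genotype")


def sds_page_matrix() -> BandMatrix:
    """Synthetic 8-band SDS-PAGE protein profile over the six genotypes.

    Reconstructed to satisfy every published constraint: bands at 85, 50,
    20 and 10 kDa monomorphic; the 59 and 2 kDa bands present only in
    Jiz-511 and Jiz-517; two further polymorphic bands placed so that the
    per-genotype totals are 5, 5, 6, 7, 7 and 6 with no unique bands.
    """
    rows = [
        ("SDS", "b85", 85, (1, 1, 1, 1, 1, 1)),
        ("SDS", "b50", 50, (1, 1, 1, 1, 1, 1)),
        ("SDS", "b20", 20, (1, 1, 1, 1, 1, 1)),
        ("SDS", "b10", 10, (1, 1, 1, 1, 1, 1)),
        ("SDS", "b59", 59, (0, 0, 0, 1, 1, 0)),
        ("SDS", "b2", 2, (0, 0, 0, 1, 1, 0)),
        ("SDS", "b45", 45, (1, 0, 1, 1, 0, 1)),
        ("SDS", "b33", 33, (0, 1, 1, 0, 1, 1)),
    ]
    records = [
        BandRecord(assay_id=a, band_id=b, fragment_size=s, presence=p)
        for a, b, s, p in rows
    ]
    return BandMatrix(list(GENOTYPES), records, unit="kDa")


def assay_specs_from_counts(
    counts: pd.DataFrame, n_genotypes: int = 6, seed: int = 0
) -> list[AssaySpec]:
    """Turn a printed per-primer count table into generator specs.

    The published UB column does not split positive from negative uniques,
    so the count is divided as evenly as possible (positives get the extra
    one).  Per-assay seeds are derived deterministically from ``seed``.
    """
    specs = []
    for i, (assay_id, row) in enumerate(counts.iterrows()):
        ub = int(row["UB"])
        n_pos = math.ceil(ub / 2)
        specs.append(
            AssaySpec(
                assay_id=str(assay_id),
                n_genotypes=n_genotypes,
                n_monomorphic=int(row["MB"]),
                n_unique_pos=n_pos,
                n_unique_neg=ub - n_pos,
                n_other_polymorphic=int(row["PB"]) - ub,
                fs_range=(int(row["fs_smaller"]), int(row["fs_larger"])),
                seed=(seed * 1_000 + i) % (2**31),
            )
        )
    return specs
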