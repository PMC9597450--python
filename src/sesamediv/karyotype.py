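"""Karyotype asymmetry analysis from per-chromosome arm measurements.

Given short- and long-arm lengths (µm) of a haploid chromosome complement
the module derives the classical descriptive and asymmetry statistics:

* per chromosome — total length ``CL = s + l``, arm ratio ``r = l/s``,
  centromeric index ``ci = s/CL``, Watanabe's M value ``(l - s)/CL``, and a
  Levan-style centromere class (nearly metacentric ``nm``, nearly
  submetacentric ``nsm(-)``, nearly subtelocentric ``nst``, nearly
  telocentric ``nt``);
* per karyotype — total haploid length (HCL), total form percent
  ``TF% = 100 * Σs / ΣCL`` and its complement the karyotype asymmetry
  percent ``AsK% = 100 * Σl / ΣCL``, Arano's symmetry
  ``S% = 100 * min(CL)/max(CL)``, mean centromeric index, Watanabe's degree
  of asymmetry ``A`` (mean M) and ``MCA = 100 A``, coefficients of
  variation of chromosome length and centromeric index (CVcl, CVci),
  Romero-Zarco's intra- and interchromosomal indices
  ``A1 = 1 - mean(s_i/l_i)`` and ``A2 = CVcl/100``, Paszko's asymmetry
  index ``AI = CVcl * CVci / 100``, the Stebbins two-way symmetry category
  and the diploid karyotype formula.

All indices are computed on the haploid measurement set; the diploid count
``2n`` is metadata used for the formula's counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateChromosomeError, UndefinedCVError

__all__ = [
    "ChromosomeMeasurement",
    "KaryotypeSet",
    "KaryotypeSummary",
    "ChromosomeDescriptors",
    "ClassThresholds",
    "chromosome_descriptors",
    "classify_chromosome",
    "karyotype_formula",
    "karyotype_summary",
    "stebbins_category",
    "ideogram_table",
    "ideogram_svg",
    "read_karyotypes",
    "summary_table",
]

# class labels; the "(−)" token (U+2212) follows cytogenetic reporting usage
NM = "nm"
NSM = "nsm(−)"
NST = "nst"
NT = "nt"
FORMULA_CLASS_ORDER = (NSM, NST, NM, NT)


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """Arm lengths of one chromosome (µm); arms normalised so l >= s."""

    index: int
    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.short_arm < 0 or self.long_arm < 0:
            raise DegenerateChromosomeError(
                f"chromosome {self.index}: negative arm length"
            )
        if self.short_arm + self.long_arm <= 0:
            raise DegenerateChromosomeError(
                f"chromosome {self.index}: zero total length"
            )
        if self.long_arm < self.short_arm:
            s, l = self.long_arm, self.short_arm
            object.__setattr__(self, "short_arm", s)
            object.__setattr__(self, "long_arm", l)

    @property
    def total_length(self) -> float:
        return self.short_arm + self.long_arm


@dataclass
class KaryotypeSet:
    """A genotype's haploid chromosome measurements plus 2n metadata."""

    genotype: str
    chromosomes: list[ChromosomeMeasurement]
    diploid_number: int | None = None

    def __post_init__(self) -> None:
        if self.diploid_number is not None:
            if self.diploid_number != 2 * len(self.chromosomes):
                raise ValueError(
                    f"{self.genotype}: 2n = {self.diploid_number} but "
                    f"{len(self.chromosomes)} haploid chromosomes measured"
                )

    @property
    def n(self) -> int:
        return len(self.chromosomes)


class ChromosomeDescriptors(NamedTuple):
    total_length: float
    arm_ratio: float  # inf for telocentric (s = 0)
    centromeric_index: float
    m_value: float


@dataclass(frozen=True)
class ClassThresholds:
    """Levan-band arm-ratio cut points for the 'nearly' centromere classes."""

    nm_max: float = 1.7
    nsm_max: float = 3.0
    nst_max: float = 7.0


def chromosome_descriptors(c: ChromosomeMeasurement) -> ChromosomeDescriptors:
    """CL, arm ratio l/s (inf when s = 0), centromeric index s/CL, M value."""
    cl = c.total_length
    r = math.inf if c.short_arm == 0 else c.long_arm / c.short_arm
    return ChromosomeDescriptors(
        total_length=cl,
        arm_ratio=r,
        centromeric_index=c.short_arm / cl,
        m_value=(c.long_arm - c.short_arm) / cl,
    )


def classify_chromosome(
    c: ChromosomeMeasurement, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Centromere class from the arm ratio; telocentrics (s = 0) are nt."""
    r = chromosome_descriptors(c).arm_ratio
    if r < thresholds.nm_max:
        return NM
    if r < thresholds.nsm_max:
        return NSM
    if r < thresholds.nst_max:
        return NST
    return NT


def karyotype_formula(
    kset: KaryotypeSet, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Diploid per-class counts, e.g. ``2 nsm (−)+12 nst+12 nm``.

    Haploid class tallies are doubled; classes appear in the fixed order
    nsm(−), nst, nm, nt, absent classes omitted.
    """
    tally = {cls: 0 for cls in FORMULA_CLASS_ORDER}
    for c in kset.chromosomes:
        tally[classify_chromosome(c, thresholds)] += 1
    parts = []
    for cls in FORMULA_CLASS_ORDER:
        if tally[cls]:
            label = "nsm (−)" if cls == NSM else cls
            parts.append(f"{2 * tally[cls]} {label}")
    return "+".join(parts)


def stebbins_category(kset: KaryotypeSet) -> str:
    """Stebbins two-way symmetry class, e.g. '2B'.

    Column letter from the largest/smallest chromosome-length ratio R
    (A: R < 2, B: 2 <= R < 4, C: R >= 4); row digit from the proportion P
    of chromosomes with arm ratio > 2 (1: P = 0; 2: 0 < P <= 0.5;
    3: 0.5 < P < 1; 4: P = 1).  Telocentrics count as arm ratio > 2.
    """
    lengths = [c.total_length for c in kset.chromosomes]
    if len(lengths) < 2:
        raise UndefinedCVError("Stebbins category needs >= 2 chromosomes")
    ratio = max(lengths) / min(lengths)
    col = "A" if ratio < 2 else ("B" if ratio < 4 else "C")
    prop = sum(
        1 for c in kset.chromosomes if chromosome_descriptors(c).arm_ratio > 2
    ) / len(lengths)
    if prop == 0:
        row = "1"
    elif prop <= 0.5:
        row = "2"
    elif prop < 1:
        row = "3"
    else:
        row = "4"
    return row + col


@dataclass(frozen=True)
class KaryotypeSummary:
    genotype: str
    n_chromosomes: int
    diploid_number: int | None
    hcl: float
    tf_percent: float
    ask_percent: float
    s_percent: float
    ci_mean: float
    a_watanabe: float
    mca: float
    cv_cl: float
    cv_ci: float
    ai: float
    a1: float
    a2: float
    stebbins: str
    formula: str


def _cv(values: np.ndarray, sample: bool = True) -> float:
    """Coefficient of variation in percent; sample (n-1) sd by default."""
    mean = values.mean()
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    sd = values.std(ddof=1 if sample else 0)
    return 100.0 * sd / mean


def karyotype_summary(
    kset: KaryotypeSet,
    thresholds: ClassThresholds = ClassThresholds(),
    sample_sd: bool = True,
) -> KaryotypeSummary:
    """All karyotype indices for one measurement set (full precision).

    CVcl / CVci use the sample (n-1) standard deviation unless
    ``sample_sd=False``.  Telocentric chromosomes contribute s/l = 0 to A1.
    """
    if kset.n < 2:
        raise UndefinedCVError(
            f"{kset.genotype}: summary needs >= 2 chromosomes"
        )
    desc = [chromosome_descriptors(c) for c in kset.chromosomes]
    cl = np.array([d.total_length for d in desc])
    ci = np.array([d.centromeric_index for d in desc])
    m = np.array([d.m_value for d in desc])
    short = np.array([c.short_arm for c in kset.chromosomes])
    long_ = np.array([c.long_arm for c in kset.chromosomes])
    hcl = float(cl.sum())
    tf = 100.0 * float(short.sum()) / hcl
    a = float(m.mean())
    cv_cl = _cv(cl, sample=sample_sd)
    cv_ci = _cv(ci, sample=sample_sd)
    return KaryotypeSummary(
        genotype=kset.genotype,
        n_chromosomes=kset.n,
        diploid_number=kset.diploid_number,
        hcl=hcl,
        tf_percent=tf,
        ask_percent=100.0 * float(long_.sum()) / hcl,
        s_percent=100.0 * float(cl.min()) / float(cl.max()),
        ci_mean=float(ci.mean()),
        a_watanabe=a,
        mca=100.0 * a,
        cv_cl=cv_cl,
        cv_ci=cv_ci,
        ai=cv_cl * cv_ci / 100.0,
        a1=1.0 - float((short / long_).mean()),
        a2=cv_cl / 100.0,
        stebbins=stebbins_category(kset),
        formula=karyotype_formula(kset, thresholds),
    )


def ideogram_table(kset: KaryotypeSet, order: str = "by_length") -> pd.DataFrame:
    """Drawing coordinates per chromosome: 0 at the short-arm telomere,
    centromere at s, end at CL.  Default order is descending total length.
    """
    if order not in ("by_length", "by_index"):
        raise ValueError(f"order must be by_length or by_index, got {order!r}")
    chroms = list(kset.chromosomes)
    if order == "by_length":
        chroms.sort(key=lambda c: (-c.total_length, c.index))
    else:
        chroms.sort(key=lambda c: c.index)
    rows = [
        {
            "position": i + 1,
            "chromosome": c.index,
            "short_arm": c.short_arm,
            "centromere": c.short_arm,
            "end": c.total_length,
            "class": classify_chromosome(c),
        }
        for i, c in enumerate(chroms)
    ]
    return pd.DataFrame(rows).set_index("position")


def ideogram_svg(kset: KaryotypeSet, order: str = "by_length") -> str:
    """Minimal deterministic SVG ideogram: one vertical bar per chromosome
    with a tick at the centromere, scaled to the longest chromosome."""
    table = ideogram_table(kset, order)
    max_len = table["end"].max()
    bar_w, gap, h = 18, 14, 220.0
    width = len(table) * (bar_w + gap) + gap
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{h + 40:.0f}" viewBox="0 0 {width} {h + 40:.0f}">'
    ]
    for i, row in enumerate(table.itertuples()):
        x = gap + i * (bar_w + gap)
        bh = h * row.end / max_len
        cen = h * row.centromere / max_len
        parts.append(
            f'<rect x="{x}" y="20" width="{bar_w}" height="{bh:.2f}" '
            f'fill="#c8c8c8" stroke="#333"/>'
        )
        parts.append(
            f'<line x1="{x - 3}" y1="{20 + cen:.2f}" x2="{x + bar_w + 3}" '
            f'y2="{20 + cen:.2f}" stroke="#b00" stroke-width="2"/>'
        )
        parts.append(
            f'<text x="{x + bar_w / 2}" y="{h + 36:.0f}" font-size="10" '
            f'text-anchor="middle">{row.chromosome}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def read_karyotypes(path: str | Path) -> list[KaryotypeSet]:
    """Read `genotype,chromosome,short_arm_um,long_arm_um` delimited text."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    need = {"genotype", "chromosome", "short_arm_um", "long_arm_um"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    out = []
    for genotype, grp in df.groupby("genotype", sort=True):
        chroms = [
            ChromosomeMeasurement(
                index=int(r.chromosome),
                short_arm=float(r.short_arm_um),
                long_arm=float(r.long_arm_um),
            )
            for r in grp.itertuples()
        ]
        out.append(
            KaryotypeSet(
                str(genotype), chroms, diploid_number=2 * len(chroms)
            )
        )
    return out


def write_karyotypes(ksets: list[KaryotypeSet], path: str | Path) -> None:
    rows = []
    for ks in ksets:
        for c in ks.chromosomes:
            rows.append(
                {
                    "genotype": ks.genotype,
                    "chromosome": c.index,
                    "short_arm_um": c.short_arm,
                    "long_arm_um": c.long_arm,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summary_table(
    ksets: list[KaryotypeSet], decimals: int = 2, **kwargs
) -> pd.DataFrame:
    """Report table over genotypes, mirroring standard karyotype tables."""
    rows = []
    for ks in ksets:
        s = karyotype_summary(ks, **kwargs)
        rows.append(
            {
                "genotype": s.genotype,
                "2n": s.diploid_number,
                "HCL_um": round(s.hcl, decimals),
                "TF_percent": round(s.tf_percent, decimals),
                "AsK_percent": round(s.ask_percent, decimals),
                "S_percent": round(s.s_percent, decimals),
                "CI": round(s.ci_mean, decimals),
                "A": round(s.a_watanabe, decimals),
                "MCA": round(s.mca, decimals),
                "CVcl": round(s.cv_cl, decimals),
                "CVci": round(s.cv_ci, decimals),
                "AI": round(s.ai, decimals),
                "Stebbins": s.stebbins,
                "A1": round(s.a1, decimals),
                "A2": round(s.a2, decimals),
                "KF": s.formula,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
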