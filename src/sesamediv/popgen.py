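"""Dominant-marker population genetics under Hardy-Weinberg equilibrium.

A dominant band cannot distinguish homozygous from heterozygous carriers,
so allele frequencies are back-calculated from the band frequency ``f``
(fraction of individuals showing the band) assuming Hardy-Weinberg
proportions: the null (band-absent) allele has frequency ``q = sqrt(1 - f)``
and the band allele ``p = 1 - q``.  Per-locus diversity statistics follow
the GenAlEx binary-data conventions:

* ``Na`` — observed number of alleles (1 for a fixed locus, else 2);
* ``Ne`` — effective number of alleles ``1 / (p**2 + q**2)``;
* ``I``  — Shannon information index ``-(p ln p + q ln q)`` (0 ln 0 = 0);
* ``He`` — expected heterozygosity ``2 p q``;
* ``uHe`` — unbiased expected heterozygosity ``[2N / (2N - 1)] He``.

Population summaries are plain means over all loci, including fixed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .band_matrix import BandMatrix
from .errors import LookupError_, UndefinedStatisticError

__all__ = [
    "Population",
    "LocusFreqs",
    "LocusStats",
    "dominant_allele_freqs",
    "locus_statistics",
    "popgen_summary",
    "populations_from_map",
    "harvest_index",
]


@dataclass(frozen=True)
class Population:
    """A labelled set of individual columns of a band matrix."""

    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise UndefinedStatisticError(f"population {self.label!r} is empty")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LocusFreqs:
    """Band frequency and the HW-derived allele frequencies at one locus."""

    f: float
    p: float
    q: float


@dataclass(frozen=True)
class LocusStats:
    na: float
    ne: float
    shannon: float
    he: float
    uhe: float


def dominant_allele_freqs(
    matrix: BandMatrix, pop: Population, locus: tuple[str, str]
) -> LocusFreqs:
    """Band frequency f in the population and q = sqrt(1 - f), p = 1 - q."""
    assay_id, band_id = locus
    rec = next(
        (
            r
            for r in matrix.records
            if r.assay_id == assay_id and r.band_id == band_id
        ),
        None,
    )
    if rec is None:
        raise LookupError_(f"unknown locus {locus!r}")
    idx = [matrix.genotype_index(m) for m in pop.members]
    f = sum(rec.presence[i] for i in idx) / len(idx)
    q = math.sqrt(1.0 - f)
    return LocusFreqs(f=f, p=1.0 - q, q=q)


def locus_statistics(freqs: LocusFreqs, n: int) -> LocusStats:
    """Na, Ne, Shannon I, He and uHe at one locus for population size ``n``."""
    if n < 1:
        raise UndefinedStatisticError("population size must be >= 1")
    p, q = freqs.p, freqs.q
    na = sum(1 for a in (p, q) if a > 0.0)
    ne = 1.0 / (p * p + q * q)
    shannon = -sum(a * math.log(a) for a in (p, q) if a > 0.0)
    he = 2.0 * p * q
    uhe = (2.0 * n / (2.0 * n - 1.0)) * he if n >= 1 else float("nan")
    return LocusStats(na=float(na), ne=ne, shannon=shannon, he=he, uhe=uhe)


def popgen_summary(
    matrix: BandMatrix, pops: list[Population], decimals: int = 3
) -> pd.DataFrame:
    """Per-population means of the locus statistics over all loci.

    Returns a DataFrame indexed by population label with columns
    ``N, Na, Ne, I, He, uHe, P_percent`` plus a ``Total`` row holding the
    mean over populations.  ``P_percent`` is the percentage of loci with
    band frequency strictly between 0 and 1 within the population.
    """
    if not matrix.records:
        raise UndefinedStatisticError("no loci in matrix")
    rows = []
    for pop in pops:
        idx = [matrix.genotype_index(m) for m in pop.members]
        n = pop.size
        acc = {"Na": 0.0, "Ne": 0.0, "I": 0.0, "He": 0.0, "uHe": 0.0}
        n_poly = 0
        for rec in matrix.records:
            f = sum(rec.presence[i] for i in idx) / n
            q = math.sqrt(1.0 - f)
            st = locus_statistics(LocusFreqs(f=f, p=1.0 - q, q=q), n)
            acc["Na"] += st.na
            acc["Ne"] += st.ne
            acc["I"] += st.shannon
            acc["He"] += st.he
            acc["uHe"] += st.uhe
            if 0.0 < f < 1.0:
                n_poly += 1
        n_loci = len(matrix.records)
        rows.append(
            {
                "population": pop.label,
                "N": n,
                "Na": acc["Na"] / n_loci,
                "Ne": acc["Ne"] / n_loci,
                "I": acc["I"] / n_loci,
                "He": acc["He"] / n_loci,
                "uHe": acc["uHe"] / n_loci,
                "P_percent": 100.0 * n_poly / n_loci,
            }
        )
    df = pd.DataFrame(rows).set_index("population")
    df.loc["Total"] = df.mean()
    return df.round(decimals)


def populations_from_map(mapping: pd.DataFrame) -> list[Population]:
    """Build populations from an ``individual,population`` two-column table."""
    if not {"individual", "population"} <= set(mapping.columns):
        raise LookupError_(
            "population map needs 'individual' and 'population' columns"
        )
    pops = []
    for label, grp in mapping.groupby("population", sort=True):
        pops.append(Population(str(label), tuple(grp["individual"].astype(str))))
    return pops


def harvest_index(seed_yield: float, stover_yield: float) -> float:
    """Harvest index: seed yield as a percent of biological yield.

    Biological yield is seed plus stover (above-ground residue) yield.
    """
    if seed_yield < 0 or stover_yield < 0:
        raise UndefinedStatisticError("yields must be non-negative")
    total = seed_yield + stover_yield
    if total == 0:
        raise UndefinedStatisticError("harvest index undefined when both yields are zero")
    return 100.0 * seed_yield / total
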