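"""Marker-informativeness indices for dominant fingerprinting assays.

For an assay (primer) scored over a panel of genotypes the standard
discriminatory-power indices are:

* ``P%`` — percent polymorphism, ``100 * PB / TAB``;
* ``PIC`` — polymorphism information content.  Two conventions are
  implemented.  The per-band dominant-marker form ``2 f (1 - f)`` (mean over
  an assay's bands, capped at 0.5) and the banding-phenotype form
  ``1 - sum_j p_j**2`` where ``p_j`` are the frequencies of the distinct
  multilocus banding patterns the assay produces.  The phenotype form can
  reach ``1 - 1/n`` and is the default, since published assay PICs for
  multi-band dominant systems routinely exceed the 0.5 per-band ceiling.
* ``EMR`` — effective multiplex ratio, ``PB * (PB / TAB)``;
* ``MI`` — marker index, ``PIC * EMR`` (unrounded PIC);
* ``Rp`` — resolving power, ``sum_b (1 - 2 |0.5 - f_b|)`` over scored bands,
  ``f_b`` being the fraction of genotypes carrying band ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .band_matrix import BandClass, BandMatrix, PrimerSummary, classify_band, summarize_assay
from .errors import DomainError, UndefinedStatisticError

__all__ = [
    "PrimerInformativeness",
    "polymorphism_percent",
    "pic_per_band",
    "pic_per_band_mean",
    "pic_phenotype",
    "emr",
    "marker_index",
    "resolving_power",
    "assay_informativeness",
    "informativeness_table",
]

PIC_MODES = ("phenotype_freq", "per_band_mean")


@dataclass(frozen=True)
class PrimerInformativeness:
    """Informativeness indices for one assay."""

    assay_id: str
    p_percent: float
    pic: float
    emr: float
    mi: float
    rp: float
    pic_mode: str


def polymorphism_percent(summary: PrimerSummary) -> float:
    """Percent polymorphism ``100 * PB / TAB``."""
    if summary.n_total == 0:
        raise UndefinedStatisticError(
            f"{summary.assay_id}: P% undefined for TAB = 0"
        )
    return 100.0 * summary.n_polymorphic / summary.n_total


def pic_per_band(f: float) -> float:
    """Dominant-marker per-band PIC, ``2 f (1 - f)``; maximal 0.5 at f = 0.5."""
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"band frequency {f} outside [0, 1]")
    return 2.0 * f * (1.0 - f)


def pic_per_band_mean(matrix: BandMatrix, assay_id: str) -> float:
    """Assay PIC as the mean per-band ``2 f (1 - f)`` over scored bands."""
    recs = [
        r
        for r in matrix.assay_records(assay_id)
        if classify_band(r) is not BandClass.ABSENT
    ]
    if not recs:
        raise UndefinedStatisticError(f"{assay_id}: no scored bands")
    return sum(pic_per_band(r.frequency) for r in recs) / len(recs)


def pic_phenotype(matrix: BandMatrix, assay_id: str) -> float:
    """Assay PIC from banding-phenotype frequencies, ``1 - sum p_j**2``.

    Each genotype's full presence/absence pattern over the assay's bands is
    one phenotype class.
    """
    recs = matrix.assay_records(assay_id)
    patterns: dict[tuple[int, ...], int] = {}
    for gi in range(matrix.n_genotypes):
        pat = tuple(r.presence[gi] for r in recs)
        patterns[pat] = patterns.get(pat, 0) + 1
    n = matrix.n_genotypes
    return 1.0 - sum((c / n) ** 2 for c in patterns.values())


def emr(summary: PrimerSummary) -> float:
    """Effective multiplex ratio ``PB * (PB / TAB)``."""
    if summary.n_total == 0:
        raise UndefinedStatisticError(
            f"{summary.assay_id}: EMR undefined for TAB = 0"
        )
    pb = summary.n_polymorphic
    return pb * (pb / summary.n_total)


def marker_index(pic: float, emr_value: float) -> float:
    """Marker index ``PIC * EMR`` (PIC at full precision, never rounded)."""
    if not 0.0 <= pic <= 1.0:
        raise DomainError(f"pic {pic} outside [0, 1]")
    if emr_value < 0:
        raise DomainError(f"emr {emr_value} negative")
    return pic * emr_value


def resolving_power(matrix: BandMatrix, assay_id: str) -> float:
    """Resolving power ``sum_b I_b`` with ``I_b = 1 - 2 |0.5 - f_b|``.

    ``f_b`` is the genotype fraction carrying band ``b``; unamplified bands
    (f = 0) contribute 0 and are skipped.
    """
    recs = matrix.assay_records(assay_id)
    rp = 0.0
    for rec in recs:
        if classify_band(rec) is BandClass.ABSENT:
            continue
        rp += 1.0 - 2.0 * abs(0.5 - rec.frequency)
    return rp


def assay_informativeness(
    matrix: BandMatrix, assay_id: str, pic_mode: str = "phenotype_freq"
) -> PrimerInformativeness:
    """All five indices for one assay under the chosen PIC convention."""
    if pic_mode not in PIC_MODES:
        raise DomainError(f"pic_mode must be one of {PIC_MODES}, got {pic_mode!r}")
    summary = summarize_assay(matrix, assay_id)
    if pic_mode == "phenotype_freq":
        pic = pic_phenotype(matrix, assay_id)
    else:
        pic = pic_per_band_mean(matrix, assay_id)
    e = emr(summary)
    return PrimerInformativeness(
        assay_id=assay_id,
        p_percent=polymorphism_percent(summary),
        pic=pic,
        emr=e,
        mi=marker_index(pic, e),
        rp=resolving_power(matrix, assay_id),
        pic_mode=pic_mode,
    )


def informativeness_table(
    matrix: BandMatrix, pic_mode: str = "phenotype_freq", decimals: int = 2
) -> pd.DataFrame:
    """Joined per-assay report: counts, size span and indices, plus Total
    and Average rows.

    The ``Total`` row sums the counts and index columns and carries the
    *pooled* polymorphism percent ``100 * sum(PB) / sum(TAB)``; the
    ``Average`` row holds arithmetic means of the per-assay values.  Both
    conventions appear in published tables, so both are emitted.
    """
    rows = []
    for assay_id in matrix.assay_ids:
        s = summarize_assay(matrix, assay_id)
        info = assay_informativeness(matrix, assay_id, pic_mode)
        rows.append(
            {
                "assay_id": assay_id,
                "MB": s.n_monomorphic,
                "UB": s.n_unique,
                "PB": s.n_polymorphic,
                "TAB": s.n_total,
                "FS_larger": s.fs_max,
                "FS_smaller": s.fs_min,
                "PIC": info.pic,
                "EMR": info.emr,
                "MI": info.mi,
                "P_percent": info.p_percent,
                "Rp": info.rp,
            }
        )
    df = pd.DataFrame(rows).set_index("assay_id")
    sums = df[["MB", "UB", "PB", "TAB", "PIC", "EMR", "MI", "Rp"]].sum()
    pooled_p = 100.0 * sums["PB"] / sums["TAB"] if sums["TAB"] else float("nan")
    total = {**sums.to_dict(), "P_percent": pooled_p, "FS_larger": None, "FS_smaller": None}
    means = df[["MB", "UB", "PB", "TAB", "PIC", "EMR", "MI", "P_percent", "Rp"]].mean()
    average = {**means.to_dict(), "FS_larger": None, "FS_smaller": None}
    df.loc["Total"] = pd.Series(total)
    df.loc["Average"] = pd.Series(average)
    num_cols = ["PIC", "EMR", "MI", "P_percent", "Rp"]
    df[num_cols] = df[num_cols].astype(float).round(decimals)
    return df
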