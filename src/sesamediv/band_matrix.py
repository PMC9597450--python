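"""Binary band matrices from dominant marker assays (ISSR, SCoT) and SDS-PAGE.

A band matrix records, for every scored band of every assay (PCR primer or
protein gel), which genotypes show the band.  Cells are strictly 0/1: only
clear, reproducible bands are scored, so no missing-data state exists.

Band classes follow the accounting used in dominant-marker fingerprinting
reports: a band present in every genotype is *monomorphic* (MB); present in
exactly one genotype it is a *positive unique* band, absent from exactly one
a *negative unique* band (together UB); any other segregating pattern is
plain polymorphic.  Unique bands are a subset of the polymorphic bands, so
MB + PB = TAB and UB <= PB for every assay.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateBandError,
    EmptyInputError,
    InsufficientGenotypesError,
    LookupError_,
    MalformedCellError,
)

__all__ = [
    "BandClass",
    "BandRecord",
    "BandMatrix",
    "PrimerSummary",
    "classify_band",
    "summarize_assay",
    "summarize_genotype",
    "unique_band_catalogue",
    "read_band_matrix",
    "write_band_matrix",
    "summary_table",
]


class BandClass(enum.Enum):
    """Classification of a single band's presence pattern."""

    MONOMORPHIC = "monomorphic"
    UNIQUE_POS = "unique_pos"
    UNIQUE_NEG = "unique_neg"
    POLYMORPHIC_OTHER = "polymorphic_other"
    ABSENT = "absent"

    @property
    def is_polymorphic(self) -> bool:
        return self in (
            BandClass.UNIQUE_POS,
            BandClass.UNIQUE_NEG,
            BandClass.POLYMORPHIC_OTHER,
        )

    @property
    def is_unique(self) -> bool:
        return self in (BandClass.UNIQUE_POS, BandClass.UNIQUE_NEG)


@dataclass(frozen=True)
class BandRecord:
    """One scored band: its assay, identity, size and presence vector."""

    assay_id: str
    band_id: str
    fragment_size: int
    presence: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.fragment_size <= 0:
            raise ValueError(
                f"fragment_size must be positive, got {self.fragment_size} "
                f"for band ({self.assay_id}, {self.band_id})"
            )
        bad = [v for v in self.presence if v not in (0, 1)]
        if bad:
            raise MalformedCellError(
                f"band ({self.assay_id}, {self.band_id}) has non-binary "
                f"presence value(s) {bad}"
            )

    @property
    def n_present(self) -> int:
        return sum(self.presence)

    @property
    def frequency(self) -> float:
        """Fraction of genotypes carrying the band."""
        return self.n_present / len(self.presence)


@dataclass
class BandMatrix:
    """An ordered genotype roster plus the band records scored over it."""

    genotypes: list[str]
    records: list[BandRecord] = field(default_factory=list)
    unit: str = "bp"

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise EmptyInputError("a band matrix needs at least one genotype")
        if self.unit not in ("bp", "kDa"):
            raise ValueError(f"unit must be 'bp' or 'kDa', got {self.unit!r}")
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.assay_id, rec.band_id)
            if key in seen:
                raise DuplicateBandError(f"duplicate band {key}")
            seen.add(key)
            if len(rec.presence) != len(self.genotypes):
                raise ValueError(
                    f"band {key} has {len(rec.presence)} presence entries "
                    f"for {len(self.genotypes)} genotypes"
                )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def assay_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.assay_id not in out:
                out.append(rec.assay_id)
        return out

    def assay_records(self, assay_id: str) -> list[BandRecord]:
        recs = [r for r in self.records if r.assay_id == assay_id]
        if not recs:
            raise LookupError_(f"unknown assay {assay_id!r}")
        return recs

    def genotype_index(self, genotype: str) -> int:
        try:
            return self.genotypes.index(genotype)
        except ValueError:
            raise LookupError_(f"unknown genotype {genotype!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Bands x genotypes 0/1 DataFrame indexed by (assay_id, band_id)."""
        idx = pd.MultiIndex.from_tuples(
            [(r.assay_id, r.band_id) for r in self.records],
            names=["assay_id", "band_id"],
        )
        return pd.DataFrame(
            [list(r.presence) for r in self.records],
            index=idx,
            columns=self.genotypes,
            dtype=int,
        )

    def profiles(self) -> pd.DataFrame:
        """Genotypes x bands 0/1 DataFrame (one row per genotype)."""
        return self.to_frame().T

    def subset_assays(self, assay_ids: Iterable[str]) -> "BandMatrix":
        wanted = list(assay_ids)
        recs = [r for r in self.records if r.assay_id in wanted]
        return BandMatrix(list(self.genotypes), recs, self.unit)


@dataclass(frozen=True)
class PrimerSummary:
    """Per-assay band accounting (MB / UB / PB / TAB and size span)."""

    assay_id: str
    n_monomorphic: int
    n_polymorphic: int
    n_unique_pos: int
    n_unique_neg: int
    n_total: int
    fs_min: int | None = None
    fs_max: int | None = None

    @property
    def n_unique(self) -> int:
        return self.n_unique_pos + self.n_unique_neg

    def __post_init__(self) -> None:
        if self.n_monomorphic + self.n_polymorphic != self.n_total:
            raise ValueError(
                f"{self.assay_id}: MB ({self.n_monomorphic}) + PB "
                f"({self.n_polymorphic}) != TAB ({self.n_total})"
            )
        if self.n_unique > self.n_polymorphic:
            raise ValueError(
                f"{self.assay_id}: UB ({self.n_unique}) exceeds PB "
                f"({self.n_polymorphic})"
            )
        if (
            self.n_total >= 1
            and self.fs_min is not None
            and self.fs_max is not None
            and self.fs_min > self.fs_max
        ):
            raise ValueError(f"{self.assay_id}: fs_min > fs_max")


def classify_band(record: BandRecord) -> BandClass:
    """Classify one band by its presence pattern.

    Present in all genotypes -> monomorphic; in exactly one -> positive
    unique; absent from exactly one -> negative unique; in none -> absent
    (never scored, excluded from TAB); anything else -> polymorphic.  With
    two genotypes the single-presence pattern counts as positive unique.
    """
    n = len(record.presence)
    if n < 2:
        raise InsufficientGenotypesError(
            f"band ({record.assay_id}, {record.band_id}): classification "
            "needs at least two genotypes"
        )
    k = record.n_present
    if k == n:
        return BandClass.MONOMORPHIC
    if k == 0:
        return BandClass.ABSENT
    if k == 1:
        return BandClass.UNIQUE_POS
    if k == n - 1:
        return BandClass.UNIQUE_NEG
    return BandClass.POLYMORPHIC_OTHER


def summarize_assay(matrix: BandMatrix, assay_id: str) -> PrimerSummary:
    """Band accounting for one assay: MB, UB (pos/neg), PB, TAB, size span.

    Bands amplified in no genotype are ignored entirely (an unscored band
    contributes to no count).
    """
    recs = matrix.assay_records(assay_id)
    counts = {cls: 0 for cls in BandClass}
    sizes: list[int] = []
    for rec in recs:
        cls = classify_band(rec)
        counts[cls] += 1
        if cls is not BandClass.ABSENT:
            sizes.append(rec.fragment_size)
    n_poly = (
        counts[BandClass.UNIQUE_POS]
        + counts[BandClass.UNIQUE_NEG]
        + counts[BandClass.POLYMORPHIC_OTHER]
    )
    n_total = counts[BandClass.MONOMORPHIC] + n_poly
    return PrimerSummary(
        assay_id=assay_id,
        n_monomorphic=counts[BandClass.MONOMORPHIC],
        n_polymorphic=n_poly,
        n_unique_pos=counts[BandClass.UNIQUE_POS],
        n_unique_neg=counts[BandClass.UNIQUE_NEG],
        n_total=n_total,
        fs_min=min(sizes) if sizes else None,
        fs_max=max(sizes) if sizes else None,
    )


def summarize_genotype(matrix: BandMatrix, genotype: str) -> dict[str, int]:
    """Per-genotype band accounting (SDS-PAGE style).

    TAB counts bands the genotype shows; MB those shared by all genotypes;
    PB the polymorphic bands this genotype shows; UB its positive uniques.
    """
    gi = matrix.genotype_index(genotype)
    tab = mb = pb = ub = 0
    for rec in matrix.records:
        if rec.presence[gi] != 1:
            continue
        tab += 1
        cls = classify_band(rec)
        if cls is BandClass.MONOMORPHIC:
            mb += 1
        else:
            pb += 1
            if cls is BandClass.UNIQUE_POS:
                ub += 1
    return {"TAB": tab, "MB": mb, "PB": pb, "UB": ub}


def unique_band_catalogue(matrix: BandMatrix) -> pd.DataFrame:
    """Per-genotype counts of positive and negative unique bands.

    Returns a DataFrame indexed by genotype with columns n_pos, n_neg,
    n_total; the grand total equals the number of unique bands in the
    matrix (each unique band is attributed to exactly one genotype).
    """
    if matrix.n_genotypes < 2:
        raise InsufficientGenotypesError("unique bands need >= 2 genotypes")
    pos = {g: 0 for g in matrix.genotypes}
    neg = {g: 0 for g in matrix.genotypes}
    for rec in matrix.records:
        cls = classify_band(rec)
        if cls is BandClass.UNIQUE_POS:
            g = matrix.genotypes[rec.presence.index(1)]
            pos[g] += 1
        elif cls is BandClass.UNIQUE_NEG:
            g = matrix.genotypes[rec.presence.index(0)]
            neg[g] += 1
    df = pd.DataFrame(
        {"n_pos": pd.Series(pos), "n_neg": pd.Series(neg)},
    ).loc[matrix.genotypes]
    df.index.name = "genotype"
    df["n_total"] = df["n_pos"] + df["n_neg"]
    return df


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Dialect: header `assay_id<sep>band_id<sep>fragment_size<sep><genotype>...`,
# one row per band, separator comma or tab (autodetected on read; the writer
# always emits tabs, sorted by assay then descending fragment size).
# ---------------------------------------------------------------------------

_META_COLS = ["assay_id", "band_id", "fragment_size"]


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()
    if not head:
        raise EmptyInputError(f"{path}: empty file")
    return "\t" if "\t" in head[0] else ","


def read_band_matrix(path: str | Path, unit: str = "bp") -> BandMatrix:
    """Read a band matrix from delimited text (comma or tab autodetected)."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: no band rows")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise EmptyInputError(f"{path}: missing column(s) {missing}")
    genotypes = [c for c in df.columns if c not in _META_COLS]
    if not genotypes:
        raise EmptyInputError(f"{path}: no genotype columns")
    records: list[BandRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = dict(zip(df.columns, row))
        presence: list[int] = []
        for g in genotypes:
            cell = str(vals[g]).strip()
            if cell not in ("0", "1"):
                raise MalformedCellError(
                    f"{path}: row {row_no}, column {g!r}: cell {cell!r} "
                    "is not 0 or 1"
                )
            presence.append(int(cell))
        records.append(
            BandRecord(
                assay_id=str(vals["assay_id"]),
                band_id=str(vals["band_id"]),
                fragment_size=int(float(vals["fragment_size"])),
                presence=tuple(presence),
            )
        )
    return BandMatrix(genotypes, records, unit=unit)


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    """Write tab-separated, sorted by assay id then descending size."""
    path = Path(path)
    order = sorted(
        matrix.records, key=lambda r: (r.assay_id, -r.fragment_size, r.band_id)
    )
    buf = io.StringIO()
    buf.write("\t".join(_META_COLS + matrix.genotypes) + "\n")
    for rec in order:
        cells = [rec.assay_id, rec.band_id, str(rec.fragment_size)]
        cells += [str(v) for v in rec.presence]
        buf.write("\t".join(cells) + "\n")
    path.write_text(buf.getvalue())


def summary_table(matrix: BandMatrix) -> pd.DataFrame:
    """MB/UB/PB/TAB and size-span table over all assays (report column order)."""
    rows = []
    for assay_id in matrix.assay_ids:
        s = summarize_assay(matrix, assay_id)
        rows.append(
            {
                "assay_id": s.assay_id,
                "MB": s.n_monomorphic,
                "UB": s.n_unique,
                "PB": s.n_polymorphic,
                "TAB": s.n_total,
                "FS_larger": s.fs_max,
                "FS_smaller": s.fs_min,
            }
        )
    return pd.DataFrame(rows).set_index("assay_id")
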