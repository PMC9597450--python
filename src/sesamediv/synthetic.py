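"""Constructive generators for band matrices and karyotypes.

The study's raw gels and metaphase measurements are not deposited, so
analyses run on synthetic data constructed to hit published summary
statistics *exactly*:

* :func:`generate_band_matrix` builds, per assay, the requested numbers of
  monomorphic, positive-unique, negative-unique and other-polymorphic
  bands, so that band accounting on the output returns the specification
  verbatim;
* :func:`generate_population_samples` expands each genotype column into
  replicate individuals with independent Bernoulli band flips, providing
  within-genotype variation for the population-genetic statistics;
* :func:`generate_karyotype` builds chromosome sets whose pooled short-arm
  fraction (TF%), uniform centromeric asymmetry (M value) or
  chromosome-length coefficient of variation matches a target — the first
  two exactly by construction, the CV analytically via a two-point length
  distribution.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_matrix import BandMatrix, BandRecord
from .errors import FeasibilityError, ParameterError
from .karyotype import ChromosomeMeasurement, KaryotypeSet

__all__ = [
    "AssaySpec",
    "KaryotypeSpec",
    "generate_band_matrix",
    "generate_population_samples",
    "generate_karyotype",
]


@dataclass(frozen=True)
class AssaySpec:
    """Target band accounting for one synthetic assay."""

    assay_id: str
    n_genotypes: int
    n_monomorphic: int = 0
    n_unique_pos: int = 0
    n_unique_neg: int = 0
    n_other_polymorphic: int = 0
    fs_range: tuple[int, int] = (100, 2000)
    seed: int = 0

    @property
    def n_total(self) -> int:
        return (
            self.n_monomorphic
            + self.n_unique_pos
            + self.n_unique_neg
            + self.n_other_polymorphic
        )

    def validate(self) -> None:
        n = self.n_genotypes
        counts = (
            self.n_monomorphic,
            self.n_unique_pos,
            self.n_unique_neg,
            self.n_other_polymorphic,
        )
        if any(c < 0 for c in counts):
            raise FeasibilityError(f"{self.assay_id}: negative band count")
        if self.n_total == 0:
            raise FeasibilityError(f"{self.assay_id}: no bands requested")
        if n < 2:
            raise FeasibilityError(f"{self.assay_id}: need >= 2 genotypes")
        if self.n_unique_neg and n < 3:
            # with 2 genotypes a single absence is also a single presence
            raise FeasibilityError(
                f"{self.assay_id}: negative uniques need >= 3 genotypes"
            )
        if self.n_other_polymorphic and n < 4:
            raise FeasibilityError(
                f"{self.assay_id}: other-polymorphic bands need >= 4 genotypes"
            )
        lo, hi = self.fs_range
        if not (0 < lo <= hi):
            raise FeasibilityError(f"{self.assay_id}: bad size range {self.fs_range}")
        if hi - lo + 1 < self.n_total:
            raise FeasibilityError(
                f"{self.assay_id}: size range too narrow for {self.n_total} "
                "distinct fragment sizes"
            )


def generate_band_matrix(
    specs: list[AssaySpec],
    genotypes: list[str] | None = None,
    unit: str = "bp",
) -> BandMatrix:
    """Build a band matrix realising every assay specification exactly.

    Fragment sizes are drawn without replacement from each spec's range so
    band identities stay unique; 'other polymorphic' patterns draw a
    presence count uniformly from 2..n-2 and a random genotype subset,
    which can never collide with the monomorphic, unique or absent classes.
    """
    if not specs:
        raise FeasibilityError("no assay specs")
    n = specs[0].n_genotypes
    for spec in specs:
        spec.validate()
        if spec.n_genotypes != n:
            raise FeasibilityError("assay specs disagree on genotype count")
    if genotypes is None:
        genotypes = [f"G{i + 1}" for i in range(n)]
    if len(genotypes) != n:
        raise FeasibilityError("genotype roster length mismatch")
    records: list[BandRecord] = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        sizes = rng.choice(
            np.arange(spec.fs_range[0], spec.fs_range[1] + 1),
            size=spec.n_total,
            replace=False,
        )
        sizes = sorted((int(s) for s in sizes), reverse=True)
        patterns: list[tuple[int, ...]] = []
        for _ in range(spec.n_monomorphic):
            patterns.append(tuple([1] * n))
        for _ in range(spec.n_unique_pos):
            row = [0] * n
            row[int(rng.integers(n))] = 1
            patterns.append(tuple(row))
        for _ in range(spec.n_unique_neg):
            row = [1] * n
            row[int(rng.integers(n))] = 0
            patterns.append(tuple(row))
        for _ in range(spec.n_other_polymorphic):
            k = int(rng.integers(2, n - 1))  # presence count in 2..n-2
            idx = rng.choice(n, size=k, replace=False)
            row = [0] * n
            for i in idx:
                row[int(i)] = 1
            patterns.append(tuple(row))
        for b, (size, pat) in enumerate(zip(sizes, patterns), start=1):
            records.append(
                BandRecord(
                    assay_id=spec.assay_id,
                    band_id=f"b{b}_{size}",
                    fragment_size=size,
                    presence=pat,
                )
            )
    return BandMatrix(list(genotypes), records, unit=unit)


def generate_population_samples(
    base: BandMatrix,
    replicates: int,
    flip_rate: float,
    seed: int = 0,
) -> BandMatrix:
    """Expand each genotype into replicate individuals with band flips.

    Every cell of every replicate is flipped independently with probability
    ``flip_rate`` (< 0.5, so replicates stay closer to their own base
    profile than to any other).  Column labels ``<genotype>_r<i>`` encode
    membership for the population map.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if not 0.0 <= flip_rate < 0.5:
        raise ParameterError(f"flip rate must be in [0, 0.5), got {flip_rate}")
    rng = np.random.default_rng(seed)
    base_arr = np.array([r.presence for r in base.records], dtype=int)
    n_bands, n_geno = base_arr.shape
    cols: list[str] = []
    data = np.zeros((n_bands, n_geno * replicates), dtype=int)
    for gi, g in enumerate(base.genotypes):
        for rep in range(replicates):
            flips = rng.random(n_bands) < flip_rate
            data[:, len(cols)] = np.where(flips, 1 - base_arr[:, gi], base_arr[:, gi])
            cols.append(f"{g}_r{rep + 1}")
    records = [
        BandRecord(
            assay_id=rec.assay_id,
            band_id=rec.band_id,
            fragment_size=rec.fragment_size,
            presence=tuple(int(v) for v in data[bi]),
        )
        for bi, rec in enumerate(base.records)
    ]
    return BandMatrix(cols, records, unit=base.unit)


@dataclass(frozen=True)
class KaryotypeSpec:
    """Targets for one synthetic karyotype.

    Exactly one of ``tf_percent`` (pooled short-arm fraction x100) and
    ``m_value`` (uniform per-chromosome (l-s)/(l+s)) fixes the arm split;
    ``cv_cl`` (chromosome-length CV, %) may be combined with either and
    fixes the length spread.  With no ``cv_cl`` the lengths are drawn
    randomly from the seed.
    """

    n_chromosomes: int = 13
    total_length: float = 100.0
    tf_percent: float | None = None
    m_value: float | None = None
    cv_cl: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 2:
            raise FeasibilityError("need >= 2 chromosomes")
        if self.total_length <= 0:
            raise FeasibilityError("total length must be positive")
        if self.tf_percent is not None and self.m_value is not None:
            raise FeasibilityError(
                "tf_percent and m_value both fix the arm split; choose one"
            )
        if self.tf_percent is None and self.m_value is None and self.cv_cl is None:
            raise FeasibilityError("no shape target given")
        if self.tf_percent is not None and not 0.0 < self.tf_percent <= 50.0:
            raise FeasibilityError(f"TF% must be in (0, 50], got {self.tf_percent}")
        if self.m_value is not None and not 0.0 <= self.m_value < 1.0:
            raise FeasibilityError(f"M value must be in [0, 1), got {self.m_value}")
        if self.cv_cl is not None and self.cv_cl < 0:
            raise FeasibilityError("cv_cl must be >= 0")


# default arm split when only a length CV is targeted
_DEFAULT_M = 0.15


def _two_point_lengths(n: int, mean: float, cv_percent: float) -> np.ndarray:
    """n lengths with exact mean and exact sample (n-1) CV.

    Half the chromosomes (rounded down) sit above the mean and the rest
    below, at offsets solving mean and sample-variance constraints in
    closed form.
    """
    n1 = n // 2
    n2 = n - n1
    sd = cv_percent / 100.0 * mean
    if sd == 0:
        return np.full(n, mean)
    # offsets +delta*n2 (n1 times) and -delta*n1 (n2 times): mean exact;
    # sample variance = delta^2 * n1 * n2 * n / (n - 1)
    delta = sd / np.sqrt(n1 * n2 * n / (n - 1.0))
    lengths = np.concatenate(
        [np.full(n1, mean + delta * n2), np.full(n2, mean - delta * n1)]
    )
    if lengths.min() <= 0:
        raise FeasibilityError(
            f"cv_cl={cv_percent} infeasible: would need non-positive lengths"
        )
    return lengths


def generate_karyotype(spec: KaryotypeSpec, genotype: str = "synthetic") -> KaryotypeSet:
    """Build a chromosome set meeting the spec's shape targets.

    TF% and M-value targets hold exactly (every chromosome is built with
    the target arm split); the CV target holds to solver precision
    (~1e-12 relative) via the two-point length construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chromosomes
    mean_len = spec.total_length / n
    if spec.cv_cl is not None:
        lengths = _two_point_lengths(n, mean_len, spec.cv_cl)
    else:
        # mild lognormal length variation, rescaled to the exact total
        raw = rng.lognormal(mean=0.0, sigma=0.25, size=n)
        lengths = raw / raw.sum() * spec.total_length
    if spec.tf_percent is not None:
        short_frac = spec.tf_percent / 100.0
    elif spec.m_value is not None:
        short_frac = (1.0 - spec.m_value) / 2.0
    else:
        short_frac = (1.0 - _DEFAULT_M) / 2.0
    chroms = [
        ChromosomeMeasurement(
            index=i + 1,
            short_arm=float(cl) * short_frac,
            long_arm=float(cl) * (1.0 - short_frac),
        )
        for i, cl in enumerate(lengths)
    ]
    return KaryotypeSet(genotype, chroms, diploid_number=2 * n)
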