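"""End-to-end orchestration: band summaries -> informativeness -> popgen ->
karyotype -> clustering, with deterministic report output.

Every number written by the pipeline is produced by the corresponding
library function; the pipeline only sequences stages, validates the
configuration and serialises tables, so the command-line path can never
drift from the library path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .band_matrix import read_band_matrix, summary_table, unique_band_catalogue
from .clustering import (
    combined_feature_matrix,
    dice_similarity_matrix,
    distance_from_similarity,
    pcoa,
    upgma,
)
from .errors import SesamedivError
from .informativeness import PIC_MODES, informativeness_table
from .karyotype import read_karyotypes, summary_table as karyotype_table
from .karyotype import ideogram_svg, ideogram_table
from .popgen import popgen_summary, populations_from_map

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline"]


class PipelineError(SesamedivError):
    """A stage failed; message names the stage and the offending record."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``band_matrices`` maps a marker-system name (e.g. ``issr``) to a
    band-matrix file; karyotype, population-map and phenotype inputs are
    optional and simply skip their stages when absent.
    """

    band_matrices: dict[str, str] = field(default_factory=dict)
    karyotype_path: str | None = None
    population_map_path: str | None = None
    pic_mode: str = "phenotype_freq"
    sample_sd: bool = True
    out_dir: str = "results"
    seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.pic_mode not in PIC_MODES:
            raise PipelineError(f"config: pic_mode must be one of {PIC_MODES}")
        if self.rounding < 0:
            raise PipelineError("config: rounding must be >= 0")
        if not self.band_matrices:
            raise PipelineError("config: at least one band matrix is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(
            {
                "band_matrices": dict(sorted(self.band_matrices.items())),
                "karyotype_path": self.karyotype_path,
                "population_map_path": self.population_map_path,
                "pic_mode": self.pic_mode,
                "sample_sd": self.sample_sd,
                "seed": self.seed,
                "rounding": self.rounding,
            },
            sort_keys=True,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of a full run, writable as a deterministic tree."""

    band_summaries: dict[str, pd.DataFrame]
    informativeness: dict[str, pd.DataFrame]
    unique_bands: dict[str, pd.DataFrame]
    popgen: dict[str, pd.DataFrame]
    karyotype: pd.DataFrame | None
    ideograms: dict[str, pd.DataFrame]
    ideogram_svgs: dict[str, str]
    similarity: dict[str, pd.DataFrame]
    newick: dict[str, str]
    ordination: dict[str, pd.DataFrame]
    combined_features: pd.DataFrame | None
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def tsv(df: pd.DataFrame, name: str) -> None:
            df.to_csv(out / name, sep="\t")

        for name, df in self.band_summaries.items():
            tsv(df, f"band_summary_{name}.tsv")
        for name, df in self.informativeness.items():
            tsv(df, f"informativeness_{name}.tsv")
        for name, df in self.unique_bands.items():
            tsv(df, f"unique_bands_{name}.tsv")
        for name, df in self.popgen.items():
            tsv(df, f"popgen_{name}.tsv")
        if self.karyotype is not None:
            tsv(self.karyotype, "karyotype_summary.tsv")
        for name, df in self.ideograms.items():
            tsv(df, f"ideogram_{name}.tsv")
        for name, svg in self.ideogram_svgs.items():
            (out / f"ideogram_{name}.svg").write_text(svg)
        for name, df in self.similarity.items():
            tsv(df, f"similarity_{name}.tsv")
        for name, tree in self.newick.items():
            (out / f"upgma_{name}.nwk").write_text(tree + "\n")
        for name, df in self.ordination.items():
            tsv(df, f"pcoa_{name}.tsv")
        if self.combined_features is not None:
            tsv(self.combined_features, "combined_features.tsv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


_log = logging.getLogger(__name__)


def _stage(manifest: dict, name: str, t0: float, n_records: int) -> None:
    # timings are logged, not written: the manifest must be byte-identical
    # across reruns of the same config
    _log.info("stage %s: %d records in %.3fs", name, n_records, time.perf_counter() - t0)
    manifest["stages"][name] = {"records": n_records}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every configured stage and return the report bundle.

    Stage failures are re-raised as :class:`PipelineError` naming the
    stage; nothing is written until every stage has succeeded, so a failed
    run leaves no partial output.
    """
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical()),
        "stages": {},
    }
    matrices = {}
    t0 = time.perf_counter()
    try:
        for name, path in sorted(config.band_matrices.items()):
            matrices[name] = read_band_matrix(path)
    except SesamedivError as exc:
        raise PipelineError(f"stage read_band_matrices: {exc}") from exc
    _stage(manifest, "read_band_matrices", t0, sum(len(m.records) for m in matrices.values()))

    band_summaries, informativeness, unique_bands = {}, {}, {}
    t0 = time.perf_counter()
    try:
        for name, m in matrices.items():
            band_summaries[name] = summary_table(m)
            informativeness[name] = informativeness_table(
                m, pic_mode=config.pic_mode, decimals=config.rounding
            )
            unique_bands[name] = unique_band_catalogue(m)
    except SesamedivError as exc:
        raise PipelineError(f"stage markers: {exc}") from exc
    _stage(manifest, "markers", t0, sum(len(df) for df in informativeness.values()))

    popgen: dict[str, pd.DataFrame] = {}
    if config.population_map_path:
        t0 = time.perf_counter()
        try:
            pmap = pd.read_csv(config.population_map_path, sep=None, engine="python")
            pops = populations_from_map(pmap)
            for name, m in matrices.items():
                popgen[name] = popgen_summary(m, pops)
        except SesamedivError as exc:
            raise PipelineError(f"stage popgen: {exc}") from exc
        _stage(manifest, "popgen", t0, len(popgen))

    karyo_df = None
    ideograms: dict[str, pd.DataFrame] = {}
    ideogram_svgs: dict[str, str] = {}
    if config.karyotype_path:
        t0 = time.perf_counter()
        try:
            ksets = read_karyotypes(config.karyotype_path)
            karyo_df = karyotype_table(
                ksets, decimals=config.rounding, sample_sd=config.sample_sd
            )
            for ks in ksets:
                ideograms[ks.genotype] = ideogram_table(ks)
                ideogram_svgs[ks.genotype] = ideogram_svg(ks)
        except SesamedivError as exc:
            raise PipelineError(f"stage karyotype: {exc}") from exc
        _stage(manifest, "karyotype", t0, len(ideograms))

    similarity, newick, ordination = {}, {}, {}
    combined = None
    t0 = time.perf_counter()
    try:
        for name, m in matrices.items():
            sim = dice_similarity_matrix(m)
            similarity[name] = sim.to_frame().round(4)
            dist = distance_from_similarity(sim)
            newick[name] = upgma(dist).newick()
            ord_ = pcoa(dist)
            df = ord_.to_frame()
            df.loc["explained_percent"] = ord_.explained_percent
            ordination[name] = df.round(4)
        rosters = {tuple(m.genotypes) for m in matrices.values()}
        if len(rosters) == 1:
            roster = set(next(iter(rosters)))
            karyo_block = (
                karyo_df
                if karyo_df is not None and set(karyo_df.index) >= roster
                else None
            )
            combined = combined_feature_matrix(list(matrices.values()), karyo_block)
    except SesamedivError as exc:
        raise PipelineError(f"stage clustering: {exc}") from exc
    _stage(manifest, "clustering", t0, len(similarity))

    return ReportBundle(
        band_summaries=band_summaries,
        informativeness=informativeness,
        unique_bands=unique_bands,
        popgen=popgen,
        karyotype=karyo_df,
        ideograms=ideograms,
        ideogram_svgs=ideogram_svgs,
        similarity=similarity,
        newick=newick,
        ordination=ordination,
        combined_features=combined,
        manifest=manifest,
    )
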