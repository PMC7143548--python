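"""End-to-end ROH analysis: QC -> detection -> inbreeding -> hotspots ->
demography, with every stage re-runnable from its intermediate files.

``run_pipeline`` is a pure function of (inputs, config): identical inputs
and configuration produce identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .demography import TMRCAScheme, classify_segments
from .detect import ROHParams, detect_roh
from .hotspots import annotate_hotspots, call_hotspots, hotspot_table, snp_incidence
from .inbreeding import (
    AutosomeExtent,
    compute_froh,
    summarize_distribution,
)
from .io import (
    GeneticMap,
    GenotypeMatrix,
    read_bed_bim_fam,
    read_gene_bed,
    read_genetic_map,
    read_ped_map,
    write_roh_table,
)
from .qc import QCParams, apply_qc

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_prefix: str | None = None
    input_format: str = "bed"  # "bed" or "ped"
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    top_fraction: float = 0.01
    genetic_map: str | None = None
    genes: str | None = None
    tmrca: TMRCAScheme = field(default_factory=TMRCAScheme)
    outdir: str = "rohscan_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QCParams(**kwargs["qc"])
        if "roh" in kwargs:
            kwargs["roh"] = ROHParams(**kwargs["roh"])
        if "tmrca" in kwargs:
            t = kwargs["tmrca"]
            kwargs["tmrca"] = TMRCAScheme(
                boundaries_cm=tuple(t["boundaries_cm"]), labels=tuple(t["labels"])
            )
        return cls(**kwargs)


@dataclass
class PipelineResult:
    genotypes: GenotypeMatrix
    qc_report: object
    segments: list
    inbreeding: object
    distribution: object
    incidence: pd.DataFrame
    hotspots: list
    demography: pd.DataFrame | None
    outputs: dict[str, Path]


def _log_params(path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"rohscan {__version__}\n")
        yaml.safe_dump(
            {
                "input_prefix": config.input_prefix,
                "input_format": config.input_format,
                "qc": dataclasses.asdict(config.qc),
                "roh": dataclasses.asdict(config.roh),
                "top_fraction": config.top_fraction,
                "genetic_map": config.genetic_map,
                "genes": config.genes,
                "tmrca": {
                    "boundaries_cm": list(config.tmrca.boundaries_cm),
                    "labels": list(config.tmrca.labels),
                },
                "seed": config.seed,
            },
            fh,
        )


def run_pipeline(
    config: PipelineConfig, genotypes: GenotypeMatrix | None = None
) -> PipelineResult:
    """Run the full analysis; writes every report under ``config.outdir``.

    A pre-loaded :class:`GenotypeMatrix` may be passed directly (e.g. a
    simulated cohort); otherwise ``input_prefix``/``input_format`` name
    the fileset to load.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "load"
    try:
        if genotypes is None:
            if config.input_format == "ped":
                genotypes = read_ped_map(
                    f"{config.input_prefix}.ped", f"{config.input_prefix}.map"
                )
            else:
                genotypes = read_bed_bim_fam(config.input_prefix)
        gmap = read_genetic_map(config.genetic_map) if config.genetic_map else None
        genes = read_gene_bed(config.genes) if config.genes else None
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError(stage, e) from e
    logger.info("loaded %d samples x %d markers", genotypes.n_samples, genotypes.n_markers)

    stage = "qc"
    try:
        clean, qc_report = apply_qc(genotypes, config.qc)
        qc_path = outdir / "qc_report.tsv"
        pd.DataFrame(qc_report.to_rows(), columns=["criterion", "count"]).to_csv(
            qc_path, sep="\t", index=False
        )
        outputs["qc_report"] = qc_path
    except Exception as e:
        raise StageError(stage, e) from e
    logger.info("QC kept %d samples x %d markers", clean.n_samples, clean.n_markers)

    stage = "detect"
    try:
        segments = detect_roh(clean, config.roh)
        hom_path = outdir / "roh.hom.tsv"
        write_roh_table(segments, hom_path)
        outputs["roh_table"] = hom_path
    except Exception as e:
        raise StageError(stage, e) from e
    logger.info("detected %d ROH segments", len(segments))

    stage = "inbreeding"
    try:
        extent = AutosomeExtent.from_markers(clean.markers)
        report = compute_froh(segments, extent, samples=clean.samples)
        summary = summarize_distribution(segments, extent, clean.n_samples)
        p1 = outdir / "froh_per_sample.tsv"
        report.per_sample.to_csv(p1, sep="\t")
        p2 = outdir / "froh_per_chromosome.tsv"
        report.per_sample_chrom.to_csv(p2, sep="\t", index=False)
        p3 = outdir / "froh_categories.tsv"
        summary.froh_cv.to_csv(p3, sep="\t", index=False)
        p4 = outdir / "roh_distribution.tsv"
        with open(p4, "w") as fh:
            summary.totals.rename("value").to_csv(fh, sep="\t", header=True)
            fh.write("\n")
            summary.per_bin.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            summary.per_chromosome.to_csv(fh, sep="\t", index=False)
        outputs.update(
            froh_per_sample=p1, froh_per_chromosome=p2, froh_categories=p3, distribution=p4
        )
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "hotspots"
    try:
        incidence = snp_incidence(segments, clean.markers, clean.n_samples)
        regions = call_hotspots(incidence, config.top_fraction)
        annotate_hotspots(regions, annotation=genes, gmap=gmap)
        table = hotspot_table(regions)
        p5 = outdir / "hotspots.tsv"
        table.to_csv(p5, sep="\t", index=False)
        outputs["hotspots"] = p5
    except Exception as e:
        raise StageError(stage, e) from e
    logger.info("called %d hotspot regions", len(regions))

    stage = "demography"
    demo = None
    try:
        if gmap is not None:
            demo = classify_segments(segments, gmap, config.tmrca, n_samples=clean.n_samples)
            p6 = outdir / "demography.tsv"
            demo.to_csv(p6, sep="\t", index=False)
            outputs["demography"] = p6
    except Exception as e:
        raise StageError(stage, e) from e

    log_path = outdir / "run_log.yaml"
    _log_params(log_path, config)
    outputs["run_log"] = log_path
    return PipelineResult(
        genotypes=clean,
        qc_report=qc_report,
        segments=segments,
        inbreeding=report,
        distribution=summary,
        incidence=incidence,
        hotspots=regions,
        demography=demo,
        outputs=outputs,
    )
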