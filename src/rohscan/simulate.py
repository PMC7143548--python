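"""Synthetic genotype cohorts with known (planted) autozygosity.

The generator emulates a 50K-array livestock cohort: ~2000 markers per
autosome on 26 autosomes (~52k markers), background genotypes in
Hardy-Weinberg proportions with per-marker allele frequencies drawn
uniformly on [0.05, 0.5], and *planted autozygous tracts* whose genetic
lengths follow the exponential distribution Exp(mean = 100/(2g)) cM
implied by a common ancestor ``g`` generations back.  Within a tract the
sample is homozygous for a single drawn haplotype; genotyping error
flips homozygous tract calls to heterozygous at rate ``genotype_error_rate``
and missingness masks calls genome-wide at rate ``missing_rate``.  A
``hotspot`` specification plants one fixed tract in a random carrier
fraction of samples, creating a population-shared ROH island.

Markers are statistically independent given their allele frequencies:
background linkage disequilibrium is deliberately not simulated (the
planted tracts supply all homozygosity structure the pipeline consumes).

Every random draw flows from ``SimConfig.seed``; equal seeds give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    canonicalize_minor,
    write_bed_bim_fam,
    write_genetic_map,
    write_ped_map,
)


@dataclass(frozen=True)
class HotspotSpec:
    """A tract shared by a fraction of the cohort (an engineered ROH island)."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_fraction: float


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 100
    n_chromosomes: int = 26
    markers_per_chromosome: int = 2000
    chromosome_length_bp: int = 100_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_f: float = 0.0
    generation_depth: float = 6.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    cm_per_mb: float = 1.0
    hotspot: HotspotSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_f", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.hotspot and not 0 <= self.hotspot.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted tracts and exact autozygous fraction per simulated sample."""

    tracts: dict[str, list[tuple[int, int, int]]]  # sample -> (chrom, start, end)
    f_true: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "chrom": c, "start_bp": a, "end_bp": b}
            for sid, tl in self.tracts.items()
            for c, a, b in tl
        ]
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    truth: SimTruth
    config: SimConfig


class InfeasibleTargetError(RuntimeError):
    """Planted-tract placement failed after bounded retries."""


_MAX_RETRIES = 1000


def _plant_tracts(cfg: SimConfig, rng: np.random.Generator, carrier: bool) -> list[tuple[int, int, int]]:
    """Non-overlapping tracts for one sample reaching the target fraction."""
    tracts: list[tuple[int, int, int]] = []
    if carrier and cfg.hotspot:
        tracts.append((cfg.hotspot.chrom, cfg.hotspot.start_bp, cfg.hotspot.end_bp))
    total_bp = cfg.n_chromosomes * cfg.chromosome_length_bp
    target_bp = cfg.target_f * total_bp
    mean_cm = 100.0 / (2.0 * cfg.generation_depth)
    planted = sum(b - a for _, a, b in tracts)
    retries = 0
    while planted < target_bp:
        length_cm = rng.exponential(mean_cm)
        length_bp = int(round(length_cm / cfg.cm_per_mb * 1e6))
        if length_bp < 1 or length_bp >= cfg.chromosome_length_bp:
            retries += 1
            if retries > _MAX_RETRIES:
                raise InfeasibleTargetError(
                    "cannot place tracts of the drawn lengths on these chromosomes"
                )
            continue
        chrom = int(rng.integers(1, cfg.n_chromosomes + 1))
        start = int(rng.integers(0, cfg.chromosome_length_bp - length_bp))
        end = start + length_bp
        overlap = any(c == chrom and a < end and start < b for c, a, b in tracts)
        if overlap:
            retries += 1
            if retries > _MAX_RETRIES:
                raise InfeasibleTargetError(
                    f"target_f={cfg.target_f} infeasible: overlap rejection exhausted"
                )
            continue
        tracts.append((chrom, start, end))
        planted += length_bp
    return tracts


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate a cohort; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    n, n_chrom, m_chrom = cfg.n_samples, cfg.n_chromosomes, cfg.markers_per_chromosome
    L = cfg.chromosome_length_bp

    # marker positions: uniform random, deduplicated, sorted per chromosome
    chrom_col, pos_col, id_col = [], [], []
    for c in range(1, n_chrom + 1):
        pos = np.unique(rng.integers(1, L, size=int(m_chrom * 1.2)))
        while pos.size < m_chrom:
            pos = np.unique(np.concatenate([pos, rng.integers(1, L, size=m_chrom)]))
        pos = np.sort(rng.choice(pos, size=m_chrom, replace=False))
        chrom_col.append(np.full(m_chrom, c))
        pos_col.append(pos)
        id_col.extend(f"snp{c}_{i}" for i in range(m_chrom))
    markers = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_col),
            "snp_id": id_col,
            "pos_bp": np.concatenate(pos_col),
        }
    )
    m = len(markers)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()

    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)

    samples = [f"S{i:04d}" for i in range(n)]
    carrier_draw = rng.random(n) < (cfg.hotspot.carrier_fraction if cfg.hotspot else 0.0)
    total_bp = n_chrom * L
    truth_tracts: dict[str, list[tuple[int, int, int]]] = {}
    f_true: dict[str, float] = {}
    chrom_offsets = {int(c): np.searchsorted(chroms, c, "left") for c in range(1, n_chrom + 1)}
    for i, sid in enumerate(samples):
        if cfg.target_f >= 1.0:
            tracts = [(c, 0, L) for c in range(1, n_chrom + 1)]
        else:
            tracts = _plant_tracts(cfg, rng, bool(carrier_draw[i]))
        truth_tracts[sid] = tracts
        f_true[sid] = sum(b - a for _, a, b in tracts) / total_bp
        for chrom, a, b in tracts:
            lo = chrom_offsets[chrom]
            hi = np.searchsorted(chroms, chrom, "right")
            l = lo + np.searchsorted(pos[lo:hi], a, "left")
            r = lo + np.searchsorted(pos[lo:hi], b, "right")
            if r > l:
                # one haplotype draw, doubled: homozygous across the tract
                hap = rng.random(r - l) < p[l:r]
                calls[i, l:r] = 2 * hap.astype(np.int8)

    if cfg.genotype_error_rate > 0:
        for i, sid in enumerate(samples):
            for chrom, a, b in truth_tracts[sid]:
                lo = chrom_offsets[chrom]
                hi = np.searchsorted(chroms, chrom, "right")
                l = lo + np.searchsorted(pos[lo:hi], a, "left")
                r = lo + np.searchsorted(pos[lo:hi], b, "right")
                if r > l:
                    sub = calls[i, l:r]
                    flip = (sub != 1) & (rng.random(r - l) < cfg.genotype_error_rate)
                    sub[flip] = 1
                    calls[i, l:r] = sub

    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = MISSING

    calls = canonicalize_minor(calls)
    gm = GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    gmap = GeneticMap.uniform({c: L for c in range(1, n_chrom + 1)}, cfg.cm_per_mb)
    return SimResult(
        genotypes=gm,
        genetic_map=gmap,
        truth=SimTruth(tracts=truth_tracts, f_true=f_true),
        config=cfg,
    )


def write_cohort(sim: SimResult, prefix) -> dict[str, Path]:
    """Write PED/MAP, BED/BIM/FAM, genetic-map TSV and truth TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_ped_map(sim.genotypes, prefix)
    write_bed_bim_fam(sim.genotypes, prefix)
    gmap_path = prefix.with_suffix(".gmap.tsv")
    write_genetic_map(sim.genetic_map, gmap_path)
    truth_path = prefix.with_suffix(".truth.tsv")
    sim.truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return {
        "ped": prefix.with_suffix(".ped"),
        "map": prefix.with_suffix(".map"),
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "gmap": gmap_path,
        "truth": truth_path,
    }


def make_gene_bed(
    intervals: list[tuple[int, int, int]],
    n_genes_per_interval: int,
    rng: np.random.Generator,
    path=None,
) -> pd.DataFrame:
    """Synthetic gene annotation: ``n_genes_per_interval`` genes placed
    wholly inside each (chrom, start, end) interval.  Test/demo fixture
    generator for :func:`rohscan.hotspots.count_genes`."""
    rows = []
    g = 0
    for chrom, start, end in intervals:
        for _ in range(n_genes_per_interval):
            span = max((end - start) // (2 * n_genes_per_interval), 1)
            a = int(rng.integers(start, max(end - span, start + 1)))
            b = min(a + span, end)
            rows.append({"chrom": chrom, "start_bp": a, "end_bp": b, "gene_id": f"GENE{g:04d}"})
            g += 1
    genes = pd.DataFrame(rows).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    if path is not None:
        genes[["chrom", "start_bp", "end_bp", "gene_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )
    return genes
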