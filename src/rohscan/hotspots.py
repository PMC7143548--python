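"""ROH islands: per-marker ROH incidence, top-percentile hotspot regions,
gene counts and recombination rates.

A marker's incidence is the percentage of cohort animals whose detected
ROH cover it.  Markers whose incidence reaches the nearest-rank top
percentile (ties at the threshold included) are selected; maximal runs
of selected markers that are *consecutive in the QC-passing marker
sequence* — no unselected marker between them — merge into hotspot
regions.  Region length is ``stop - start``; a single-marker region has
length 0 and an undefined recombination rate (rendered "/").

Markers with zero incidence are never selected, even when the percentile
threshold degenerates to 0: a hotspot requires some ROH coverage, and an
all-zero track would otherwise "select" the whole genome through the
tie rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneticMap, ROHSegment


@dataclass
class HotspotRegion:
    """A merged run of top-percentile-incidence markers."""

    chrom: int
    start_bp: int
    stop_bp: int
    n_snp: int
    n_genes: int | None = None
    recomb_rate_cm_per_mb: float | None = None

    @property
    def length_bp(self) -> int:
        return self.stop_bp - self.start_bp


def snp_incidence(
    segments: list[ROHSegment], markers: pd.DataFrame, n_samples: int
) -> pd.DataFrame:
    """Per-marker ROH incidence track.

    A marker is covered by a segment of the same sample when
    ``start_bp <= position <= end_bp`` (closed interval); each sample
    contributes at most once per marker even if its segments overlap.
    Returns the marker table extended with ``n_covered`` and
    ``incidence_pct`` columns.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    chrom_set = set(markers["chrom"].tolist())
    for s in segments:
        if s.chrom not in chrom_set:
            raise KeyError(f"segment chromosome {s.chrom} not in marker map")

    track = markers.copy().reset_index(drop=True)
    n_covered = np.zeros(len(track), dtype=np.int64)
    chroms = track["chrom"].to_numpy()
    pos = track["pos_bp"].to_numpy()

    by_sample_chrom: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append((s.start_bp, s.end_bp))

    chrom_slice = {
        int(c): (np.searchsorted(chroms, c, "left"), np.searchsorted(chroms, c, "right"))
        for c in np.unique(chroms)
    }
    diff = np.zeros(len(track) + 1, dtype=np.int64)
    for (sample, chrom), ivals in by_sample_chrom.items():
        lo_c, hi_c = chrom_slice[chrom]
        cpos = pos[lo_c:hi_c]
        # merge per-sample intervals so overlap never double-counts
        ivals.sort()
        merged: list[list[int]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            l = lo_c + int(np.searchsorted(cpos, a, "left"))
            r = lo_c + int(np.searchsorted(cpos, b, "right"))
            if r > l:
                diff[l] += 1
                diff[r] -= 1
    n_covered = np.cumsum(diff[:-1])
    track["n_covered"] = n_covered
    track["incidence_pct"] = 100.0 * n_covered / n_samples
    return track


def call_hotspots(track: pd.DataFrame, top_fraction: float = 0.01) -> list[HotspotRegion]:
    """Select top-percentile markers and merge consecutive ones into regions.

    The threshold is the smallest incidence attained by the top
    ``ceil(top_fraction * n_markers)`` markers (nearest-rank percentile);
    every marker at or above it is selected, so threshold ties are all
    kept.  Zero-incidence markers are never selected.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if len(track) == 0:
        raise ValueError("empty incidence track")
    inc = track["incidence_pct"].to_numpy()
    k = math.ceil(top_fraction * len(track))
    threshold = np.sort(inc)[::-1][k - 1]
    selected = (inc >= threshold) & (inc > 0)

    regions: list[HotspotRegion] = []
    idx = np.flatnonzero(selected)
    if idx.size == 0:
        return regions
    chroms = track["chrom"].to_numpy()
    pos = track["pos_bp"].to_numpy()
    brk = np.flatnonzero((np.diff(idx) != 1) | (np.diff(chroms[idx]) != 0))
    for run in np.split(idx, brk + 1):
        regions.append(
            HotspotRegion(
                chrom=int(chroms[run[0]]),
                start_bp=int(pos[run[0]]),
                stop_bp=int(pos[run[-1]]),
                n_snp=run.size,
            )
        )
    return regions


def count_genes(region: HotspotRegion, annotation: pd.DataFrame) -> int:
    """Genes whose [start, end] interval intersects the region's closed
    interval; an abutting gene (gene.start == region.stop) counts."""
    if annotation is None or len(annotation) == 0:
        return 0
    hit = (
        (annotation["chrom"] == region.chrom)
        & (annotation["start_bp"] <= region.stop_bp)
        & (annotation["end_bp"] >= region.start_bp)
    )
    return int(hit.sum())


def region_recomb_rate(region: HotspotRegion, gmap: GeneticMap) -> float | None:
    """Mean recombination rate (cM/Mb) across the region; None (undefined)
    for zero-length single-marker regions."""
    if region.chrom not in gmap.anchors:
        raise KeyError(f"chromosome {region.chrom} absent from genetic map")
    if region.length_bp == 0:
        return None
    d_cm = float(gmap.cm_at(region.chrom, region.stop_bp)) - float(
        gmap.cm_at(region.chrom, region.start_bp)
    )
    return d_cm / (region.length_bp / 1e6)


def annotate_hotspots(
    regions: list[HotspotRegion],
    annotation: pd.DataFrame | None = None,
    gmap: GeneticMap | None = None,
) -> list[HotspotRegion]:
    """Fill gene counts and recombination rates in place; returns regions."""
    for r in regions:
        if annotation is not None:
            r.n_genes = count_genes(r, annotation)
        if gmap is not None:
            r.recomb_rate_cm_per_mb = region_recomb_rate(r, gmap)
    return regions


def hotspot_table(regions: list[HotspotRegion]) -> pd.DataFrame:
    """Render regions as a table (one row per region, numbered from 1);
    undefined recombination rates render as '/'."""
    return pd.DataFrame(
        {
            "no": range(1, len(regions) + 1),
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "stop_bp": [r.stop_bp for r in regions],
            "length_bp": [r.length_bp for r in regions],
            "n_snp": [r.n_snp for r in regions],
            "n_genes": ["." if r.n_genes is None else r.n_genes for r in regions],
            "cm_per_mb": [
                "/" if r.recomb_rate_cm_per_mb is None else f"{r.recomb_rate_cm_per_mb:.2f}"
                for r in regions
            ],
        }
    )
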