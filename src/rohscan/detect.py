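"""Scanning-window detection of runs of homozygosity.

The algorithm follows the PLINK ``--homozyg`` scheme: a window of
``window_snp`` consecutive markers slides one marker at a time along each
chromosome of each sample; a window *qualifies* when it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls.
Each marker's hit rate is the fraction of windows covering it that
qualify; markers with hit rate >= ``window_hit_threshold`` are
run-eligible.  Maximal stretches of consecutive eligible markers, split
wherever two adjacent markers are more than ``max_gap_kb`` apart, become
segments if they carry at least ``min_snp`` markers, span at least
``min_length_kb``, and are at least as dense as one marker per
``max_density_kb_per_snp``.

Window smoothing means an isolated heterozygous or missing call can sit
*inside* a reported run — the per-window allowances, not a per-segment
cap, control how much residual heterozygosity a run may carry.

A chromosome with fewer markers than ``window_snp`` is scanned with a
single window of all its markers.  Segment length is
``end_bp - start_bp`` (first to last marker position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, ROHSegment


@dataclass(frozen=True)
class ROHParams:
    """Detection parameters; defaults are the PLINK v1.9 scanning-window
    defaults combined with the segment criteria typical of 50K-array
    livestock studies (>= 1 Mb, >= 40 SNPs, <= 1 Mb gap, >= 1 SNP/100 kb)."""

    window_snp: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    min_snp: int = 40
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 100.0

    def __post_init__(self) -> None:
        if min(
            self.window_snp,
            self.window_hit_threshold,
            self.min_snp,
            self.min_length_kb,
            self.max_gap_kb,
            self.max_density_kb_per_snp,
        ) <= 0:
            raise ValueError("ROH parameters must be positive")
        if self.window_max_het >= self.window_snp:
            raise ValueError("window_max_het must be smaller than window_snp")


def _eligible_markers(row: np.ndarray, window_snp: int, max_het: int, max_missing: int,
                      hit_threshold: float) -> np.ndarray:
    """Boolean run-eligibility per marker for one sample on one chromosome."""
    m = row.size
    w = min(window_snp, m)
    het = (row == 1).astype(np.int64)
    mis = (row == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    nw = m - w + 1
    starts = np.arange(nw)
    qual = ((chet[starts + w] - chet[starts]) <= max_het) & (
        (cmis[starts + w] - cmis[starts]) <= max_missing
    )
    cqual = np.concatenate([[0], np.cumsum(qual)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, nw - 1)
    total = hi - lo + 1
    n_qual = cqual[hi + 1] - cqual[lo]
    return n_qual / total >= hit_threshold


def _stretch_to_segments(
    eligible: np.ndarray,
    pos: np.ndarray,
    snp_ids: np.ndarray,
    chrom: int,
    sample_id: str,
    fid: str,
    params: ROHParams,
) -> list[ROHSegment]:
    """Candidate stretches -> gap split -> segment filters."""
    segs: list[ROHSegment] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return segs
    # break at non-consecutive marker indices or bp gaps above the cap
    gap_bp = params.max_gap_kb * 1000
    brk = np.flatnonzero((np.diff(idx) != 1) | (np.diff(pos[idx]) > gap_bp))
    for run in np.split(idx, brk + 1):
        n_snp = run.size
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        length_kb = (end - start) / 1000
        if n_snp < params.min_snp:
            continue
        if length_kb < params.min_length_kb:
            continue
        if length_kb / n_snp > params.max_density_kb_per_snp:
            continue
        segs.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=chrom,
                start_bp=start,
                end_bp=end,
                n_snp=n_snp,
                snp_first=str(snp_ids[run[0]]),
                snp_last=str(snp_ids[run[-1]]),
                fid=fid,
            )
        )
    return segs


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH for every sample; output sorted by (sample order,
    chromosome, start position)."""
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    chroms = gm.markers["chrom"].to_numpy()
    pos = gm.markers["pos_bp"].to_numpy()
    ids = gm.markers["snp_id"].to_numpy()

    segments: list[ROHSegment] = []
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        cpos, cids = pos[sel], ids[sel]
        for i, sample in enumerate(gm.samples):
            row = gm.calls[i, sel]
            eligible = _eligible_markers(
                row,
                params.window_snp,
                params.window_max_het,
                params.window_max_missing,
                params.window_hit_threshold,
            )
            segments.extend(
                _stretch_to_segments(
                    eligible, cpos, cids, int(chrom), sample, gm.fids[i], params
                )
            )
    order = {s: i for i, s in enumerate(gm.samples)}
    segments.sort(key=lambda s: (order[s.sample_id], s.chrom, s.start_bp))
    return segments


def brute_force_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Reference implementation by direct enumeration (test oracle).

    Evaluates the detection contract literally — every window listed,
    every hit rate formed from explicit window membership — with no
    incremental bookkeeping.  Intended for small instances only.
    """
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    segments: list[ROHSegment] = []
    for i, sample in enumerate(gm.samples):
        for chrom in sorted(set(gm.markers["chrom"])):
            sub = gm.markers[gm.markers["chrom"] == chrom]
            pos = [int(p) for p in sub["pos_bp"]]
            snp_ids = list(sub["snp_id"])
            row = [int(c) for c in gm.calls[i, sub.index.to_numpy()]]
            m = len(row)
            w = min(params.window_snp, m)
            windows = [list(range(s, s + w)) for s in range(m - w + 1)]
            qualifies = []
            for win in windows:
                hets = sum(1 for j in win if row[j] == 1)
                miss = sum(1 for j in win if row[j] == MISSING)
                qualifies.append(
                    hets <= params.window_max_het and miss <= params.window_max_missing
                )
            eligible = []
            for j in range(m):
                # a window covers j iff j lies between its first and last marker
                covering = [
                    q for win, q in zip(windows, qualifies) if win[0] <= j <= win[-1]
                ]
                hit_rate = sum(covering) / len(covering)
                eligible.append(hit_rate >= params.window_hit_threshold)
            # maximal eligible stretches, split at big gaps
            stretches: list[list[int]] = []
            current: list[int] = []
            for j in range(m):
                if not eligible[j]:
                    if current:
                        stretches.append(current)
                        current = []
                    continue
                if current and pos[j] - pos[current[-1]] > params.max_gap_kb * 1000:
                    stretches.append(current)
                    current = []
                current.append(j)
            if current:
                stretches.append(current)
            for run in stretches:
                n_snp = len(run)
                start, end = pos[run[0]], pos[run[-1]]
                length_kb = (end - start) / 1000
                if (
                    n_snp >= params.min_snp
                    and length_kb >= params.min_length_kb
                    and length_kb / n_snp <= params.max_density_kb_per_snp
                ):
                    segments.append(
                        ROHSegment(
                            sample_id=sample,
                            chrom=int(chrom),
                            start_bp=start,
                            end_bp=end,
                            n_snp=n_snp,
                            snp_first=str(snp_ids[run[0]]),
                            snp_last=str(snp_ids[run[-1]]),
                            fid=gm.fids[i],
                        )
                    )
    return segments
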