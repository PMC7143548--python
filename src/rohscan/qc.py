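"""Marker and sample quality control for SNP-array genotypes.

Filters mirror standard array-QC practice for ROH studies: individual
call rate, per-marker call rate ("call frequency"), minor allele
frequency, and an exact Hardy-Weinberg equilibrium test.  The sample
filter runs first (as PLINK orders --mind before --geno); marker filters
are then evaluated on the surviving samples, each marker tallied under
the first criterion it fails (call rate, then MAF, then HWE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .io import MISSING, GenotypeMatrix


class EmptyCohortError(ValueError):
    """QC removed every sample or every marker."""


@dataclass(frozen=True)
class QCParams:
    """Thresholds for :func:`apply_qc`.

    Samples are dropped when call rate <= ``min_sample_call_rate``
    (kept when strictly above, i.e. 'individual call rate > 0.9').
    Markers are dropped when call rate < ``min_snp_call_rate``, when
    MAF < ``min_maf``, or when the exact HWE p-value <= ``min_hwe_p``
    (kept when strictly above the p threshold).
    """

    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_sample_call_rate: float = 0.9

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_maf", "min_hwe_p", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_markers_in: int = 0
    samples_removed_call_rate: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_maf: int = 0
    markers_removed_hwe: int = 0
    n_samples_out: int = 0
    n_markers_out: int = 0

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("samples_in", self.n_samples_in),
            ("samples_removed_call_rate", self.samples_removed_call_rate),
            ("samples_out", self.n_samples_out),
            ("markers_in", self.n_markers_in),
            ("markers_removed_call_rate", self.markers_removed_call_rate),
            ("markers_removed_maf", self.markers_removed_maf),
            ("markers_removed_hwe", self.markers_removed_hwe),
            ("markers_out", self.n_markers_out),
        ]


def _hwe_weights(n: int, k: int) -> tuple[list[int], int]:
    """Integer enumeration weights over heterozygote counts.

    For ``n`` diploids carrying ``k`` copies of the rarer allele, the
    probability of ``h`` heterozygotes conditional on the allele counts is
    proportional to ``n! / (hom_major! h! hom_minor!) * 2**h``.  Returns
    (weights aligned to h = h_min, h_min+2, ..., h_max; h_min).
    """
    h_min = k % 2
    h_max = min(k, 2 * n - k)
    weights = []
    h = h_min
    hom_minor = (k - h) // 2
    w = math.comb(n, h) * math.comb(n - h, hom_minor) * (1 << h)
    while True:
        weights.append(w)
        if h + 2 > h_max:
            break
        hom_minor = (k - h) // 2
        hom_major = n - h - hom_minor
        # exact integer recurrence: w(h+2) = w(h) * 4*M*m / ((h+1)(h+2))
        w = w * 4 * hom_major * hom_minor // ((h + 1) * (h + 2))
        h += 2
    return weights, h_min


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic marker.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts, the probabilities of configurations no more
    likely than the observed one.  Computed in exact integer arithmetic;
    a monomorphic marker (a single possible configuration) returns 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("HWE test undefined: no genotypes observed")
    k = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    weights, h_min = _hwe_weights(n, k)
    w_obs = weights[(n_het - h_min) // 2]
    num = sum(w for w in weights if w <= w_obs)
    den = sum(weights)
    # exact rational -> correctly rounded float; p in (0, 1]
    return float(Fraction(num, den))


def apply_qc(gm: GenotypeMatrix, params: QCParams = QCParams()) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples then markers; returns the surviving matrix and tallies.

    Raises :class:`EmptyCohortError` if nothing survives a stage.
    Applying the same parameters to the output is a no-op on any cohort
    whose call rates are not re-shuffled by the marker removal (idempotence).
    """
    report = QCReport(n_samples_in=gm.n_samples, n_markers_in=gm.n_markers)
    obs = gm.calls != MISSING

    sample_rate = obs.mean(axis=1) if gm.n_markers else np.ones(gm.n_samples)
    keep_samples = sample_rate > params.min_sample_call_rate
    report.samples_removed_call_rate = int((~keep_samples).sum())
    if not keep_samples.any():
        raise EmptyCohortError("sample call-rate filter removed every sample")

    calls = gm.calls[keep_samples]
    obs = obs[keep_samples]
    n = calls.shape[0]

    marker_rate = obs.mean(axis=0)
    n_obs = obs.sum(axis=0)
    dosage_sum = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, dosage_sum / (2 * n_obs), 0.0)
    maf = np.minimum(freq, 1 - freq)

    keep = np.ones(gm.n_markers, dtype=bool)
    fail_rate = marker_rate < params.min_snp_call_rate
    fail_maf = ~fail_rate & (maf < params.min_maf)
    report.markers_removed_call_rate = int(fail_rate.sum())
    report.markers_removed_maf = int(fail_maf.sum())
    keep &= ~fail_rate & ~fail_maf

    n_hwe = 0
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        het = int((col == 1).sum())
        hom0 = int((col == 0).sum())
        hom2 = int((col == 2).sum())
        if hom0 + het + hom2 == 0:
            continue  # fully missing marker already failed call rate
        if hwe_exact_p(hom0, het, hom2) <= params.min_hwe_p:
            keep[j] = False
            n_hwe += 1
    report.markers_removed_hwe = n_hwe

    if not keep.any():
        raise EmptyCohortError("marker filters removed every marker")
    out = gm.subset(np.flatnonzero(keep_samples), np.flatnonzero(keep))
    report.n_samples_out = out.n_samples
    report.n_markers_out = out.n_markers
    return out, report
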