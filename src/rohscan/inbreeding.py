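"""ROH-based genomic inbreeding coefficients and distribution summaries.

The genomic inbreeding coefficient of an animal is

    F_ROH = L_ROH / L_AUT

where ``L_ROH`` is the summed length of its ROH and ``L_AUT`` the length
of the autosomal genome covered by the markers.  Restricted to one
chromosome the same ratio gives the chromosomal coefficient
``F_ROHOAR = L_ROHOAR / L_OAR``.  By default the denominators are the
first-to-last marker span per chromosome of the QC-passing marker set;
an extent built from nominal chromosome lengths can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ROHSegment

#: default ROH length categories in Mb, left-closed: [1,5), [5,10), [10,20), [20,inf)
DEFAULT_LENGTH_BINS_MB: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, float("inf"))


def category_labels(bins_mb=DEFAULT_LENGTH_BINS_MB) -> list[str]:
    labels = []
    for lo, hi in zip(bins_mb[:-1], bins_mb[1:]):
        labels.append(f">{lo:g}Mb" if np.isinf(hi) else f"{lo:g}-{hi:g}Mb")
    return labels


def assign_category(length_mb: float, bins_mb=DEFAULT_LENGTH_BINS_MB) -> str:
    """Left-closed bin label for one segment length."""
    labels = category_labels(bins_mb)
    for lo, hi, lab in zip(bins_mb[:-1], bins_mb[1:], labels):
        if lo <= length_mb < hi:
            return lab
    raise ValueError(f"segment length {length_mb} Mb below the category range")


@dataclass
class AutosomeExtent:
    """Marker-covered length per autosome (bp); ``l_aut`` is their sum."""

    l_oar: dict[int, int]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.l_oar.values()):
            raise ValueError("chromosome extents must be positive")

    @property
    def l_aut(self) -> int:
        return sum(self.l_oar.values())

    @classmethod
    def from_markers(cls, markers: pd.DataFrame) -> "AutosomeExtent":
        """Span (last - first marker position) per chromosome."""
        span = markers.groupby("chrom")["pos_bp"].agg(lambda p: int(p.max() - p.min()))
        return cls(l_oar={int(c): int(v) for c, v in span.items()})

    @classmethod
    def from_lengths(cls, lengths: dict[int, int]) -> "AutosomeExtent":
        """Nominal per-chromosome lengths (e.g. assembly sizes)."""
        return cls(l_oar=dict(lengths))


@dataclass
class InbreedingReport:
    """Per-sample inbreeding coefficients.

    ``per_sample`` has columns ``n_roh``, ``l_roh_bp``, ``froh`` plus one
    ``froh_<category>`` column per length bin; ``per_sample_chrom`` holds
    ``l_rohoar_bp`` and ``f_rohoar`` for every (sample, chromosome) with
    at least one segment.
    """

    per_sample: pd.DataFrame
    per_sample_chrom: pd.DataFrame
    bins_mb: tuple[float, ...] = DEFAULT_LENGTH_BINS_MB
    extent: AutosomeExtent | None = None


def compute_froh(
    segments: list[ROHSegment],
    extent: AutosomeExtent,
    samples: list[str] | None = None,
    bins_mb=DEFAULT_LENGTH_BINS_MB,
) -> InbreedingReport:
    """Genomic inbreeding coefficients from detected segments.

    Samples absent from ``segments`` (but listed in ``samples``) get
    F_ROH = 0.  Per-category coefficients use the same L_AUT denominator,
    so the category columns sum exactly to the overall F_ROH; per-
    chromosome coefficients use that chromosome's extent.
    """
    for s in segments:
        if s.chrom not in extent.l_oar:
            raise KeyError(f"segment chromosome {s.chrom} absent from extent")
    if samples is None:
        samples = sorted({s.sample_id for s in segments})
    labels = category_labels(bins_mb)

    idx = pd.Index(samples, name="sample_id")
    per_sample = pd.DataFrame(0.0, index=idx, columns=["n_roh", "l_roh_bp", "froh"]
                              + [f"froh_{lab}" for lab in labels])
    chrom_rows: dict[tuple[str, int], int] = {}
    for s in segments:
        per_sample.at[s.sample_id, "n_roh"] += 1
        per_sample.at[s.sample_id, "l_roh_bp"] += s.length_bp
        lab = assign_category(s.length_mb, bins_mb)
        per_sample.at[s.sample_id, f"froh_{lab}"] += s.length_bp
        chrom_rows[(s.sample_id, s.chrom)] = chrom_rows.get((s.sample_id, s.chrom), 0) + s.length_bp

    l_aut = extent.l_aut
    per_sample["froh"] = per_sample["l_roh_bp"] / l_aut
    for lab in labels:
        per_sample[f"froh_{lab}"] /= l_aut
    per_sample["n_roh"] = per_sample["n_roh"].astype(int)
    per_sample["l_roh_bp"] = per_sample["l_roh_bp"].astype(np.int64)

    per_sample_chrom = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "chrom": chrom,
                "l_rohoar_bp": bp,
                "f_rohoar": bp / extent.l_oar[chrom],
            }
            for (sid, chrom), bp in sorted(chrom_rows.items(), key=lambda kv: (samples.index(kv[0][0]), kv[0][1]))
        ],
        columns=["sample_id", "chrom", "l_rohoar_bp", "f_rohoar"],
    )
    return InbreedingReport(per_sample=per_sample, per_sample_chrom=per_sample_chrom,
                            bins_mb=tuple(bins_mb), extent=extent)


@dataclass
class DistributionSummary:
    """Cohort-level ROH distribution tables."""

    totals: pd.Series
    per_bin: pd.DataFrame
    per_chromosome: pd.DataFrame
    froh_cv: pd.DataFrame


def summarize_distribution(
    segments: list[ROHSegment],
    extent: AutosomeExtent,
    n_samples: int,
    bins_mb=DEFAULT_LENGTH_BINS_MB,
) -> DistributionSummary:
    """Cohort summary: totals, per-length-bin and per-chromosome tables.

    Per-chromosome coverage follows the two-step convention used in
    ROH surveys: mean summed ROH length among the animals that carry at
    least one ROH on that chromosome, divided by the chromosome length.
    Per-category F_ROH statistics (mean/CV) are computed over the animals
    that possess at least one segment in that category.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "length_bp": [s.length_bp for s in segments],
            "length_mb": [s.length_mb for s in segments],
        }
    )
    labels = category_labels(bins_mb)
    n_seg = len(df)

    per_animal_total = df.groupby("sample_id")["length_mb"].sum() if n_seg else pd.Series(dtype=float)
    totals = pd.Series(
        {
            "n_segments": float(n_seg),
            "mean_segments_per_animal": n_seg / n_samples,
            "mean_segment_length_mb": df["length_mb"].mean() if n_seg else 0.0,
            "mean_total_length_mb": per_animal_total.mean() if n_seg else 0.0,
            "max_total_length_mb": per_animal_total.max() if n_seg else 0.0,
            "n_animals_with_roh": float(per_animal_total.size),
        }
    )

    bin_rows = []
    if n_seg:
        df["category"] = [assign_category(x, bins_mb) for x in df["length_mb"]]
    for lab in labels:
        sub = df[df["category"] == lab] if n_seg else df
        carriers = sub.groupby("sample_id")["length_mb"].sum() if len(sub) else pd.Series(dtype=float)
        bin_rows.append(
            {
                "category": lab,
                "n_segments": len(sub),
                "pct_segments": 100 * len(sub) / n_seg if n_seg else 0.0,
                "mean_sum_mb": carriers.mean() if len(carriers) else 0.0,
                "n_animals": len(carriers),
            }
        )
    per_bin = pd.DataFrame(bin_rows)

    chrom_rows = []
    for chrom in sorted(extent.l_oar):
        sub = df[df["chrom"] == chrom] if n_seg else df
        per_animal = sub.groupby("sample_id")["length_bp"].sum() if len(sub) else pd.Series(dtype=float)
        mean_len = per_animal.mean() if len(per_animal) else 0.0
        chrom_rows.append(
            {
                "chrom": chrom,
                "n_segments": len(sub),
                "pct_coverage": 100 * mean_len / extent.l_oar[chrom],
            }
        )
    per_chromosome = pd.DataFrame(chrom_rows)

    # coefficient of variation (100*sd/mean) of each F_ROH column, over
    # animals carrying >=1 segment in the category
    report = compute_froh(segments, extent, bins_mb=bins_mb) if n_seg else None
    cv_rows = []
    if report is not None:
        cols = [f"froh_{lab}" for lab in labels] + ["froh"]
        names = labels + [f">{bins_mb[0]:g}Mb(all)"]
        for col, name in zip(cols, names):
            vals = report.per_sample[col]
            vals = vals[vals > 0] if col != "froh" else vals[report.per_sample["n_roh"] > 0]
            mean = vals.mean() if len(vals) else 0.0
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            cv_rows.append(
                {
                    "category": name,
                    "mean": mean,
                    "cv_pct": 100 * sd / mean if mean > 0 else 0.0,
                    "n_animals": len(vals),
                }
            )
    froh_cv = pd.DataFrame(cv_rows, columns=["category", "mean", "cv_pct", "n_animals"])
    return DistributionSummary(totals=totals, per_bin=per_bin,
                               per_chromosome=per_chromosome, froh_cv=froh_cv)
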