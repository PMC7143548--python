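"""Genetic lengths of ROH and generation-depth (TMRCA) classes.

An autozygous tract inherited from a common ancestor ``g`` generations
back has expected genetic length 100/(2g) cM, so a tract of ``l`` cM
points to a most recent common ancestor ``g = 100 / (2 l)`` generations
ago.  ROH genetic lengths therefore sort into generation-depth classes;
the defaults used here are the Thompson-derived convention common in
sheep ROH surveys:

    > 10 cM        -> "<5"  generations
    (5, 10] cM     -> "5-10"
    (2.5, 5] cM    -> "10-20"
    (1.25, 2.5] cM -> "20-40"
    <= 1.25 cM     -> "unresolved" (beyond the array's resolution)

Class intervals are left-open/right-closed in cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneticMap, ROHSegment


@dataclass(frozen=True)
class TMRCAScheme:
    """Ordered cM boundaries (strictly decreasing) and class labels.

    ``labels`` has one more entry than ``boundaries_cm``; segment with
    genetic length l falls in class i where
    boundaries[i-1] >= l > boundaries[i] (l > boundaries[0] -> class 0,
    l <= boundaries[-1] -> last class).
    """

    boundaries_cm: tuple[float, ...] = (10.0, 5.0, 2.5, 1.25)
    labels: tuple[str, ...] = ("<5", "5-10", "10-20", "20-40", "unresolved")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries_cm) + 1:
            raise ValueError("need one more label than boundaries")
        if any(b <= a for a, b in zip(self.boundaries_cm[1:], self.boundaries_cm[:-1])) or any(
            a <= b for a, b in zip(self.boundaries_cm[:-1], self.boundaries_cm[1:])
        ):
            raise ValueError("boundaries must be strictly decreasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be unique")

    def classify(self, length_cm: float) -> str:
        for b, lab in zip(self.boundaries_cm, self.labels):
            if length_cm > b:
                return lab
        return self.labels[-1]


def genetic_length(segment: ROHSegment, gmap: GeneticMap) -> float:
    """cM(end) - cM(start) by linear interpolation on the genetic map."""
    return float(gmap.cm_at(segment.chrom, segment.end_bp)) - float(
        gmap.cm_at(segment.chrom, segment.start_bp)
    )


def expected_generations(length_cm: float) -> float:
    """Expected TMRCA (generations) of an autozygous tract of ``length_cm``:
    g = 100 / (2 l)."""
    if length_cm <= 0:
        raise ValueError(f"genetic length must be positive, got {length_cm}")
    return 100.0 / (2.0 * length_cm)


def classify_segments(
    segments: list[ROHSegment],
    gmap: GeneticMap,
    scheme: TMRCAScheme = TMRCAScheme(),
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Tally segments per generation-depth class.

    Returns one row per class (empty input -> empty table) with segment
    count, mean per-animal count and fraction of all segments.  The
    per-animal denominator is ``n_samples`` when given, otherwise the
    number of distinct animals among the segments.
    """
    if not segments:
        return pd.DataFrame(columns=["class", "n_segments", "mean_per_animal", "fraction"])
    classes = [scheme.classify(genetic_length(s, gmap)) for s in segments]
    denom = n_samples if n_samples else len({s.sample_id for s in segments})
    total = len(segments)
    rows = []
    for lab in scheme.labels:
        n = classes.count(lab)
        rows.append(
            {
                "class": lab,
                "n_segments": n,
                "mean_per_animal": n / denom,
                "fraction": n / total,
            }
        )
    return pd.DataFrame(rows)
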