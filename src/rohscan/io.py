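"""Genotype, map and annotation I/O.

File formats handled here: PLINK text (PED/MAP), PLINK 1 binary
(BED/BIM/FAM, SNP-major), a tab-separated genetic map (chromosome,
position in bp, cumulative cM), a 4-column gene BED, and the
``.hom``-style ROH segment table.

Coding conventions established at load time and relied on by every
downstream module:

* genotype calls are the dosage of the per-marker *minor* allele:
  0/2 = the two homozygotes, 1 = heterozygote, ``MISSING`` (-1) = no call;
* markers are sorted by (chromosome, position) with strictly increasing
  positions within a chromosome;
* only autosomes (positive integer chromosome labels) are retained;
  sex chromosomes, mitochondrial and unplaced markers are dropped;
* interval lengths throughout the package are ``end - start`` in bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

#: columns of a marker table (``GenotypeMatrix.markers``)
MARKER_COLUMNS = ("chrom", "snp_id", "pos_bp")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort, samples x markers.

    Attributes
    ----------
    samples : list of str
        Sample (individual) identifiers, in input order.
    markers : pandas.DataFrame
        One row per marker with columns ``chrom`` (int), ``snp_id`` (str),
        ``pos_bp`` (int) and optionally ``cm``; sorted by
        (chrom, pos_bp), positions strictly increasing per chromosome.
    calls : numpy.ndarray of int8, shape (n_samples, n_markers)
        Minor-allele dosage in {0, 1, 2} or ``MISSING``.
    fids : list of str
        PLINK family identifiers (defaults to the sample ids).
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    fids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fids is None:
            self.fids = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, MISSING}")
        validate_marker_map(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx, dtype=np.intp)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx, dtype=np.intp)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=self.markers.iloc[mi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, mi)],
            fids=[self.fids[i] for i in si],
        )


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check marker-table invariants; raise ``FormatError`` on violation."""
    for col in MARKER_COLUMNS:
        if col not in markers.columns:
            raise FormatError(f"marker table lacks column {col!r}")
    by_chrom = markers.groupby("chrom", sort=False)["pos_bp"]
    if (by_chrom.diff().dropna() <= 0).any():
        raise FormatError(
            "marker positions must be strictly increasing within a chromosome "
            "(duplicate or unsorted positions)"
        )
    if "cm" in markers.columns:
        cm_ok = markers.groupby("chrom", sort=False)["cm"].diff().dropna()
        if (cm_ok < 0).any():
            raise FormatError("genetic positions (cM) decrease with bp position")


class GeneticMap:
    """Piecewise-linear bp -> cM map, one anchor set per chromosome.

    Interpolation is linear between anchors with constant extrapolation
    beyond the outermost anchors (``numpy.interp`` semantics).
    """

    def __init__(self, anchors: dict[int, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise FormatError(
                    f"chromosome {chrom}: at least 2 anchors required for "
                    f"interpolation, got {bp.size}"
                )
            order = np.argsort(bp, kind="stable")
            bp, cm = bp[order], cm[order]
            if (np.diff(bp) <= 0).any():
                raise FormatError(f"chromosome {chrom}: duplicate bp anchors")
            if (np.diff(cm) < 0).any():
                row = int(np.flatnonzero(np.diff(cm) < 0)[0]) + 1
                raise FormatError(
                    f"chromosome {chrom}: cM decreases at anchor row {row} "
                    f"(bp={bp[row]}, cM={cm[row]})"
                )
            self.anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.anchors)

    def cm_at(self, chrom: int, pos_bp) -> np.ndarray | float:
        """Genetic position in cM at physical position(s) ``pos_bp``."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom} absent from genetic map")
        bp, cm = self.anchors[chrom]
        return np.interp(pos_bp, bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths: dict[int, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: ``cm_per_mb`` centiMorgan per megabase."""
        return cls(
            {
                c: (np.array([0, length]), np.array([0.0, length / 1e6 * cm_per_mb]))
                for c, length in chrom_lengths.items()
            }
        )


@dataclass(frozen=True)
class ROHSegment:
    """One detected run of homozygosity.

    ``start_bp``/``end_bp`` are the positions of the first and last marker
    in the run; ``length_bp = end_bp - start_bp`` (package-wide length
    convention).
    """

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int
    snp_first: str = "."
    snp_last: str = "."
    fid: str = "."

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabulate ROH segments (one row each) as a DataFrame."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": np.array([s.chrom for s in segments], dtype=np.int64),
            "start_bp": np.array([s.start_bp for s in segments], dtype=np.int64),
            "end_bp": np.array([s.end_bp for s in segments], dtype=np.int64),
            "n_snp": np.array([s.n_snp for s in segments], dtype=np.int64),
            "length_bp": np.array([s.length_bp for s in segments], dtype=np.int64),
            "length_mb": np.array([s.length_mb for s in segments], dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def _parse_chrom(label: str) -> int | None:
    """Positive integer chromosome label, else None (non-autosomal)."""
    try:
        c = int(label)
    except ValueError:
        return None
    return c if c >= 1 else None


def _read_map(map_path) -> tuple[pd.DataFrame, np.ndarray]:
    raw = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    if raw.shape[1] != 4:
        raise FormatError(f"{map_path}: MAP file must have 4 columns")
    chrom = raw["chrom"].map(_parse_chrom)
    keep = chrom.notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d non-autosomal markers from %s", n_drop, map_path)
    markers = pd.DataFrame(
        {
            "chrom": chrom[keep].astype(int).to_numpy(),
            "snp_id": raw.loc[keep, "snp_id"].to_numpy(),
            "pos_bp": raw.loc[keep, "pos_bp"].astype(np.int64).to_numpy(),
            "cm": raw.loc[keep, "cm"].astype(float).to_numpy(),
        }
    )
    return markers, keep


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray):
    order = np.lexsort((markers["pos_bp"].to_numpy(), markers["chrom"].to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    return markers, calls[:, order]


def _orient_to_minor(dosage_a1: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Flip per-marker coding so calls count the observed minor allele.

    Ties in observed allele counts are broken lexicographically: the
    alphabetically smaller allele name is treated as minor.
    """
    calls = dosage_a1.copy()
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    count_a1 = np.where(obs, calls, 0).sum(axis=0)
    count_a2 = 2 * n_obs - count_a1
    # monomorphic markers code their single observed allele (dosage 2)
    both_seen = (count_a1 > 0) & (count_a2 > 0)
    flip = np.where(
        both_seen,
        (count_a1 > count_a2) | ((count_a1 == count_a2) & (a2 < a1)),
        (count_a1 == 0) & (count_a2 > 0),
    )
    if flip.any():
        cols = np.flatnonzero(flip)
        sub = calls[:, cols]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        calls[:, cols] = sub
    return calls


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Load a PLINK text fileset, recoding alleles to minor-allele dosage.

    ``0 0`` allele pairs (and any pair containing a ``0``) become
    ``MISSING``.  Markers failing to align to an autosome (non-integer or
    non-positive chromosome labels) are dropped with a logged count.
    """
    markers, keep = _read_map(map_path)
    n_markers_total = keep.size

    fids, iids, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers_total:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers_total} "
                    f"fields (6 + 2 alleles per MAP marker), got {len(parts)}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U8").reshape(len(rows), n_markers_total, 2)
    alleles = alleles[:, keep, :]

    n, m = alleles.shape[:2]
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype="U8")
    a2 = np.empty(m, dtype="U8")
    for j in range(m):
        pair = alleles[:, j, :]
        called = ~(pair == "0").any(axis=1)
        uniq = np.unique(pair[called])
        if uniq.size > 2:
            raise FormatError(
                f"marker {markers['snp_id'].iat[j]!r}: {uniq.size} distinct "
                f"alleles observed; biallelic markers required"
            )
        obs = list(uniq) if uniq.size else ["A"]
        if len(obs) == 1:
            obs.append("B" if obs[0] != "B" else "C")  # placeholder major
        a, b = sorted(obs)
        a1[j], a2[j] = a, b
        calls[called, j] = (pair[called] == a).sum(axis=1)
    calls = _orient_to_minor(calls, a1, a2)
    markers, calls = _sort_markers(markers, calls)
    return GenotypeMatrix(samples=iids, markers=markers, calls=calls, fids=fids)


def write_ped_map(gm: GenotypeMatrix, prefix) -> None:
    """Write PLINK PED/MAP; dosage allele rendered 'A', the other 'B'."""
    prefix = Path(prefix)
    gm.markers.assign(
        cm=gm.markers["cm"] if "cm" in gm.markers.columns else 0
    )[["chrom", "snp_id", "cm", "pos_bp"]].to_csv(
        prefix.with_suffix(".map"), sep="\t", header=False, index=False
    )
    pair = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, (fid, iid) in enumerate(zip(gm.fids, gm.samples)):
            geno = " ".join(pair[int(c)] for c in gm.calls[i])
            fh.write(f"{fid} {iid} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

# 2-bit codes in a SNP-major .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE_A1 = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_A1_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_bed_bim_fam(prefix) -> GenotypeMatrix:
    """Load a PLINK 1 binary fileset (SNP-major); same call semantics as
    :func:`read_ped_map`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n, m_total = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes "
            f"(expected SNP-major PLINK v1.00)"
        )
    bytes_per_marker = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_marker * m_total:
        raise FormatError(f"{prefix.with_suffix('.bed')}: truncated genotype block")
    body = body.reshape(m_total, bytes_per_marker)
    # unpack 2-bit fields, sample-within-byte little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m_total, -1)[:, :n]
    dosage_a1 = _CODE_TO_DOSAGE_A1[codes].T  # (n, m)

    chrom = bim["chrom"].map(_parse_chrom)
    keep = chrom.notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d non-autosomal markers from %s", n_drop, prefix)
    markers = pd.DataFrame(
        {
            "chrom": chrom[keep].astype(int).to_numpy(),
            "snp_id": bim.loc[keep, "snp_id"].to_numpy(),
            "pos_bp": bim.loc[keep, "pos_bp"].astype(np.int64).to_numpy(),
            "cm": bim.loc[keep, "cm"].astype(float).to_numpy(),
        }
    )
    dosage_a1 = dosage_a1[:, keep]
    calls = _orient_to_minor(
        dosage_a1, bim.loc[keep, "a1"].to_numpy(), bim.loc[keep, "a2"].to_numpy()
    )
    markers, calls = _sort_markers(markers, calls)
    return GenotypeMatrix(
        samples=list(fam["iid"]), markers=markers, calls=calls, fids=list(fam["fid"])
    )


def write_bed_bim_fam(gm: GenotypeMatrix, prefix) -> None:
    """Write a PLINK 1 binary fileset (SNP-major, A1 = dosage allele 'A')."""
    prefix = Path(prefix)
    bim = gm.markers.assign(
        cm=gm.markers["cm"] if "cm" in gm.markers.columns else 0, a1="A", a2="B"
    )
    bim[["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in zip(gm.fids, gm.samples):
            fh.write(f"{fid} {iid} 0 0 0 -9\n")

    n, m = gm.n_samples, gm.n_markers
    code = np.empty((m, n), dtype=np.uint8)
    calls_t = gm.calls.T
    for dosage, c in _DOSAGE_A1_TO_CODE.items():
        code[calls_t == dosage] = c
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    quads = code.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# genetic map / gene BED / ROH table
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> GeneticMap:
    """Read a tab-separated genetic map (chromosome, position_bp, cM).

    A header line is tolerated.  Rows are sorted per chromosome; a
    chromosome with a single anchor, duplicate bp or decreasing cM is a
    validation error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 tab-separated columns (chrom, bp, cM)")
    first = df.iloc[0]
    try:
        int(first[1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    anchors: dict[int, tuple[list, list]] = {}
    for _, row in df.iterrows():
        chrom = _parse_chrom(str(row[0]))
        if chrom is None:
            continue
        anchors.setdefault(chrom, ([], []))
        anchors[chrom][0].append(int(row[1]))
        anchors[chrom][1].append(float(row[2]))
    if not anchors:
        raise FormatError(f"{path}: no autosomal map rows")
    return GeneticMap({c: (np.array(bp), np.array(cm)) for c, (bp, cm) in anchors.items()})


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos_bp\tcm\n")
        for chrom in gmap.chromosomes:
            bp, cm = gmap.anchors[chrom]
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t{c:g}\n")


def read_gene_bed(path) -> pd.DataFrame:
    """Read a 4-column gene BED (chrom, start, end, gene_id).

    Coordinates are taken verbatim (treated as opaque, matching whatever
    build the genotype positions use); intervals are validated and the
    table sorted by (chrom, start).
    """
    genes = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start_bp", "end_bp", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    chrom = genes["chrom"].map(_parse_chrom)
    genes = genes[chrom.notna()].assign(chrom=chrom[chrom.notna()].astype(int))
    genes = genes.astype({"start_bp": np.int64, "end_bp": np.int64})
    if (genes["end_bp"] < genes["start_bp"]).any():
        raise FormatError(f"{path}: gene interval with end < start")
    return genes.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)


_HOM_COLUMNS = ["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP"]


def write_roh_table(segments, path) -> None:
    """Write ROH segments as a PLINK ``.hom``-style TSV.

    ``KB = (POS2 - POS1) / 1000`` per the package length convention.
    An empty segment list yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_HOM_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.fid}\t{s.sample_id}\t{s.chrom}\t{s.snp_first}\t{s.snp_last}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.length_bp / 1000:g}\t{s.n_snp}\n"
            )


def read_roh_table(path) -> list[ROHSegment]:
    """Re-parse a ``.hom``-style TSV written by :func:`write_roh_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str, "SNP1": str, "SNP2": str})
    return [
        ROHSegment(
            sample_id=r.IID,
            chrom=int(r.CHR),
            start_bp=int(r.POS1),
            end_bp=int(r.POS2),
            n_snp=int(r.NSNP),
            snp_first=r.SNP1,
            snp_last=r.SNP2,
            fid=r.FID,
        )
        for r in df.itertuples()
    ]


def canonicalize_minor(calls: np.ndarray) -> np.ndarray:
    """Flip markers whose coded allele is the observed major so that calls
    again count the minor allele (used after simulation).

    Matches the reader convention: polymorphic markers code the rarer
    allele (ties keep the coded allele, which the writers name 'A');
    monomorphic markers code their single observed allele.
    """
    calls = np.asarray(calls, dtype=np.int8).copy()
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    count = np.where(obs, calls, 0).sum(axis=0)
    other = 2 * n_obs - count
    both_seen = (count > 0) & (other > 0)
    flip = np.where(both_seen, count > other, (count == 0) & (other > 0))
    cols = np.flatnonzero(flip)
    if cols.size:
        sub = calls[:, cols]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        calls[:, cols] = sub
    return calls
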