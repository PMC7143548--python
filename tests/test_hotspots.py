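import numpy as np
import pandas as pd
import pytest

from rohscan import (
    GeneticMap,
    HotspotRegion,
    ROHSegment,
    call_hotspots,
    count_genes,
    hotspot_table,
    region_recomb_rate,
    snp_incidence,
)

MB = 1_000_000


def marker_table(positions, chrom=None):
    positions = np.asarray(positions, dtype=np.int64)
    chrom = np.ones_like(positions) if chrom is None else np.asarray(chrom)
    return pd.DataFrame(
        {"chrom": chrom, "snp_id": [f"m{i}" for i in range(len(positions))],
         "pos_bp": positions}
    )


def track_from(positions, incidence_pct, chrom=None):
    t = marker_table(positions, chrom)
    t["incidence_pct"] = incidence_pct
    t["n_covered"] = 0
    return t


class TestSnpIncidence:
    def test_zero_segments_zero_everywhere(self):
        track = snp_incidence([], marker_table([100, 200, 300]), n_samples=5)
        assert (track["incidence_pct"] == 0).all()

    def test_full_cohort_coverage_is_100(self):
        markers = marker_table([100, 200, 300])
        segs = [ROHSegment(f"s{i}", 1, 50, 250, 10) for i in range(4)]
        track = snp_incidence(segs, markers, n_samples=4)
        assert track["incidence_pct"].tolist() == [100.0, 100.0, 0.0]

    def test_three_of_ten_is_30pct(self):
        markers = marker_table([100, 200])
        segs = [ROHSegment(f"s{i}", 1, 150, 260, 10) for i in range(3)]
        track = snp_incidence(segs, markers, n_samples=10)
        assert track["incidence_pct"].tolist() == [0.0, 30.0]

    def test_closed_interval_endpoints_covered(self):
        markers = marker_table([100, 200, 300])
        segs = [ROHSegment("s", 1, 100, 300, 3)]
        track = snp_incidence(segs, markers, n_samples=1)
        assert (track["n_covered"] == 1).all()

    def test_overlapping_segments_of_one_sample_count_once(self):
        markers = marker_table([100, 200, 300])
        segs = [ROHSegment("s", 1, 50, 250, 3), ROHSegment("s", 1, 150, 350, 3)]
        track = snp_incidence(segs, markers, n_samples=1)
        assert track["n_covered"].max() == 1

    def test_unknown_chromosome_errors(self):
        with pytest.raises(KeyError):
            snp_incidence([ROHSegment("s", 9, 0, 100, 3)], marker_table([10]), 1)


class TestCallHotspots:
    def test_single_nonzero_marker_gives_length_zero_region(self):
        # the single-SNP hotspot pattern: length 0, one marker, rate "/"
        track = track_from(
            [28_000_000, 28_969_704, 29_500_000], [0.0, 8.0, 0.0]
        )
        regions = call_hotspots(track, top_fraction=0.5)
        assert len(regions) == 1
        (r,) = regions
        assert r.length_bp == 0 and r.n_snp == 1
        table = hotspot_table(regions)
        assert table["cm_per_mb"].iloc[0] == "/"

    def test_two_adjacent_selected_markers_merge(self):
        track = track_from(
            [32_000_000, 32_945_561, 32_982_579, 33_500_000],
            [1.0, 9.0, 9.0, 1.0],
        )
        regions = call_hotspots(track, top_fraction=0.5)
        assert len(regions) == 1
        assert regions[0].length_bp == 37_018 and regions[0].n_snp == 2

    def test_intervening_unselected_marker_splits_regions(self):
        track = track_from(
            [1 * MB, 2 * MB, 3 * MB], [9.0, 1.0, 9.0]
        )
        regions = call_hotspots(track, top_fraction=0.5)
        assert len(regions) == 2

    def test_uniform_incidence_selects_all_one_region_per_chromosome(self):
        track = track_from(
            [1, 2, 3, 1, 2], [7.0] * 5, chrom=[1, 1, 1, 2, 2]
        )
        regions = call_hotspots(track, top_fraction=0.01)
        assert len(regions) == 2
        assert sum(r.n_snp for r in regions) == 5

    def test_all_zero_track_yields_no_regions(self):
        track = track_from([1, 2, 3], [0.0, 0.0, 0.0])
        assert call_hotspots(track, top_fraction=0.5) == []

    def test_n_snp_conserved(self):
        rng = np.random.default_rng(8)
        inc = rng.choice([0.0, 2.0, 5.0, 9.0], size=400, p=[0.5, 0.3, 0.15, 0.05])
        pos = np.cumsum(rng.integers(1, 100_000, size=400))
        chrom = np.repeat([1, 2], 200)
        track = track_from(pos, inc, chrom)
        regions = call_hotspots(track, top_fraction=0.05)
        k = int(np.ceil(0.05 * 400))
        threshold = np.sort(inc)[::-1][k - 1]
        n_selected = int(((inc >= threshold) & (inc > 0)).sum())
        assert sum(r.n_snp for r in regions) == n_selected

    def test_bad_top_fraction_errors(self):
        track = track_from([1], [1.0])
        for bad in (0, 1, -0.5, 2):
            with pytest.raises(ValueError):
                call_hotspots(track, top_fraction=bad)


class TestCountGenes:
    annotation = pd.DataFrame(
        {
            "chrom": [1, 1, 1, 1, 1],
            "start_bp": [100, 500, 900, 2000, 5000],
            "end_bp": [200, 800, 1200, 2500, 6000],
            "gene_id": list("abcde"),
        }
    )

    def test_empty_annotation(self):
        r = HotspotRegion(1, 0, 1000, 5)
        assert count_genes(r, pd.DataFrame(columns=self.annotation.columns)) == 0

    def test_abutting_gene_counted(self):
        r = HotspotRegion(1, 1500, 2000, 5)  # gene d starts exactly at stop
        assert count_genes(r, self.annotation) == 1

    def test_inside_and_straddling(self):
        # genes b, c inside/straddling [400, 1000]; a ends at 200, excluded
        r = HotspotRegion(1, 400, 1000, 5)
        assert count_genes(r, self.annotation) == 2

    def test_wrong_chromosome_not_counted(self):
        r = HotspotRegion(2, 0, 10_000, 5)
        assert count_genes(r, self.annotation) == 0


class TestRecombRate:
    def test_uniform_map_rate_one(self):
        gmap = GeneticMap.uniform({1: 100 * MB}, cm_per_mb=1.0)
        r = HotspotRegion(1, 10 * MB, 14 * MB, 9)
        assert region_recomb_rate(r, gmap) == pytest.approx(1.0)

    def test_zero_length_region_undefined(self):
        gmap = GeneticMap.uniform({1: 100 * MB})
        r = HotspotRegion(1, 5 * MB, 5 * MB, 1)
        assert region_recomb_rate(r, gmap) is None

    def test_piecewise_linear_interpolation(self):
        # anchors (0,0), (2Mb,1), (4Mb,3); region 1-3 Mb: (2.0-0.5)/2 = 0.75
        gmap = GeneticMap({1: ([0, 2 * MB, 4 * MB], [0.0, 1.0, 3.0])})
        r = HotspotRegion(1, 1 * MB, 3 * MB, 20)
        assert region_recomb_rate(r, gmap) == pytest.approx(0.75)

    def test_missing_chromosome_errors(self):
        gmap = GeneticMap.uniform({1: 100 * MB})
        with pytest.raises(KeyError):
            region_recomb_rate(HotspotRegion(3, 0, MB, 5), gmap)


def test_marker_permutation_invariance():
    rng = np.random.default_rng(15)
    pos = np.cumsum(rng.integers(1, 100_000, size=200))
    inc = rng.choice([0.0, 3.0, 9.0], size=200, p=[0.7, 0.25, 0.05])
    track = track_from(pos, inc)
    regions = call_hotspots(track, top_fraction=0.05)
    perm = rng.permutation(200)
    shuffled = track.iloc[perm].sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
    regions2 = call_hotspots(shuffled, top_fraction=0.05)
    assert [(r.chrom, r.start_bp, r.stop_bp, r.n_snp) for r in regions] == [
        (r.chrom, r.start_bp, r.stop_bp, r.n_snp) for r in regions2
    ]
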