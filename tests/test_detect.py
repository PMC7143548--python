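import numpy as np
import pytest

from rohscan import (
    MISSING,
    ROHParams,
    SimConfig,
    brute_force_roh,
    detect_roh,
    simulate_cohort,
)

from conftest import build_matrix, random_matrix


def seg_key(s):
    return (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snp)


class TestDetectBasic:
    def test_perfect_run_single_segment(self):
        # 100 homozygous markers at uniform 50 kb spacing over ~5 Mb
        calls = np.zeros((1, 100), dtype=np.int8)
        gm = build_matrix(calls, positions=1 + 50_000 * np.arange(100))
        segs = detect_roh(gm)
        assert len(segs) == 1
        (s,) = segs
        assert s.n_snp == 100
        assert s.start_bp == 1 and s.end_bp == 1 + 50_000 * 99
        assert s.length_bp == s.end_bp - s.start_bp

    def test_periodic_heterozygotes_kill_runs(self):
        # every 10th call het: windows hold ~5 hets >> allowance, hit rates
        # collapse and no min_snp stretch survives (checked against oracle)
        calls = np.zeros((1, 100), dtype=np.int8)
        calls[0, ::10] = 1
        gm = build_matrix(calls, positions=1 + 50_000 * np.arange(100))
        assert detect_roh(gm) == []
        assert brute_force_roh(gm) == []

    def test_short_span_fails_length_filter(self):
        # 60 homozygous markers spanning 900 kb: density and count fine,
        # length 900 kb < 1000 kb
        calls = np.zeros((1, 60), dtype=np.int8)
        pos = np.linspace(1, 900_001, 60).astype(np.int64)
        gm = build_matrix(calls, positions=pos)
        assert detect_roh(gm) == []

    def test_gap_splitting(self):
        # homozygous chromosome with a 2 Mb gap in the middle: two runs,
        # each long enough on its own
        pos = np.concatenate(
            [1 + 30_000 * np.arange(50), 4_000_000 + 30_000 * np.arange(50)]
        )
        gm = build_matrix(np.zeros((1, 100), dtype=np.int8), positions=pos)
        segs = detect_roh(gm)
        assert len(segs) == 2
        assert segs[0].n_snp == 50 and segs[1].n_snp == 50

    def test_low_density_rejected(self):
        # 40 markers spanning 6 Mb -> 150 kb per SNP > 100 kb cap
        calls = np.zeros((1, 40), dtype=np.int8)
        pos = np.linspace(1, 6_000_001, 40).astype(np.int64)
        gm = build_matrix(calls, positions=pos)
        assert detect_roh(gm) == []

    def test_all_missing_sample_no_segments(self):
        calls = np.full((1, 100), MISSING, dtype=np.int8)
        gm = build_matrix(calls, positions=1 + 40_000 * np.arange(100))
        assert detect_roh(gm) == []
        assert brute_force_roh(gm) == []

    def test_single_marker_chromosome(self):
        gm = build_matrix(np.zeros((1, 1), dtype=np.int8))
        assert detect_roh(gm) == []
        assert brute_force_roh(gm) == []

    def test_short_chromosome_uses_full_window(self):
        # 45 markers < window_snp=50: single all-marker window
        calls = np.zeros((1, 45), dtype=np.int8)
        gm = build_matrix(calls, positions=1 + 40_000 * np.arange(45))
        segs = detect_roh(gm, ROHParams(min_snp=45))
        assert len(segs) == 1 and segs[0].n_snp == 45
        assert [seg_key(s) for s in brute_force_roh(gm, ROHParams(min_snp=45))] == [
            seg_key(s) for s in segs
        ]

    def test_interior_het_smoothed_into_run(self):
        # one isolated het inside a long homozygous run stays run-eligible
        calls = np.zeros((1, 100), dtype=np.int8)
        calls[0, 50] = 1
        gm = build_matrix(calls, positions=1 + 50_000 * np.arange(100))
        segs = detect_roh(gm)
        assert len(segs) == 1 and segs[0].n_snp == 100

    def test_empty_matrix_errors(self):
        gm = build_matrix(np.zeros((1, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            detect_roh(gm.subset(sample_idx=[]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_matrix(
            rng,
            n_samples=int(rng.integers(1, 5)),
            n_markers=int(rng.integers(60, 300)),
            hom_prob=float(rng.uniform(0.85, 0.995)),
            missing_prob=0.02,
            n_chrom=int(rng.integers(1, 4)),
        )
        params = ROHParams(
            window_snp=int(rng.integers(10, 60)),
            min_snp=int(rng.integers(10, 50)),
            min_length_kb=float(rng.choice([200, 500, 1000])),
        )
        fast = sorted(seg_key(s) for s in detect_roh(gm, params))
        slow = sorted(seg_key(s) for s in brute_force_roh(gm, params))
        assert fast == slow


@pytest.fixture(scope="module")
def cohort():
    sim = simulate_cohort(
        SimConfig(n_samples=12, n_chromosomes=3, markers_per_chromosome=2000,
                  target_f=0.08, generation_depth=5, seed=123)
    )
    return sim.genotypes


class TestProperties:
    def test_monotonic_in_min_length_and_min_snp(self, cohort):
        base = len(detect_roh(cohort, ROHParams()))
        longer = len(detect_roh(cohort, ROHParams(min_length_kb=2000)))
        more_snps = len(detect_roh(cohort, ROHParams(min_snp=80)))
        assert longer <= base and more_snps <= base
        assert base > 0

    def test_sample_permutation_preserves_per_sample_segments(self, cohort):
        perm = np.random.default_rng(9).permutation(cohort.n_samples)
        shuffled = cohort.subset(sample_idx=perm)
        by_sample = {}
        for s in detect_roh(cohort):
            by_sample.setdefault(s.sample_id, set()).add(seg_key(s))
        by_sample_perm = {}
        for s in detect_roh(shuffled):
            by_sample_perm.setdefault(s.sample_id, set()).add(seg_key(s))
        assert by_sample == by_sample_perm

    def test_planted_tract_recovery_zero_error(self):
        # every planted tract >= 2 Mb and >= 60 markers is recovered with
        # endpoints within one window span of truth
        sim = simulate_cohort(
            SimConfig(n_samples=25, n_chromosomes=4, markers_per_chromosome=2500,
                      target_f=0.06, generation_depth=4, genotype_error_rate=0.0,
                      missing_rate=0.0, seed=77)
        )
        gm = sim.genotypes
        segs = detect_roh(gm)
        by_sample = {}
        for s in segs:
            by_sample.setdefault(s.sample_id, []).append(s)
        markers = gm.markers
        window_span_bp = 50 * 100_000_000 // 2500 * 2  # window_snp * spacing, x2 slack
        checked = 0
        for sid, tracts in sim.truth.tracts.items():
            for chrom, a, b in tracts:
                in_tract = markers[(markers["chrom"] == chrom)
                                   & (markers["pos_bp"] >= a) & (markers["pos_bp"] <= b)]
                if b - a < 2_000_000 or len(in_tract) < 60:
                    continue
                checked += 1
                hits = [s for s in by_sample.get(sid, [])
                        if s.chrom == chrom and s.start_bp < b and s.end_bp > a]
                assert hits, f"tract {sid} {chrom}:{a}-{b} not recovered"
                cover_start = min(h.start_bp for h in hits)
                cover_end = max(h.end_bp for h in hits)
                assert abs(cover_start - a) <= window_span_bp
                assert abs(cover_end - b) <= window_span_bp
        assert checked > 20
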