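import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan import MISSING, QCParams, apply_qc, hwe_exact_p
from rohscan.qc import EmptyCohortError

from conftest import build_matrix


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent exact HWE p-value by direct enumeration with Fractions.

    For each feasible heterozygote count h (fixed allele counts), the
    conditional probability is
    P(h) = [n! / (hom_maj! h! hom_min!)] 2^h / sum over h' of the same.
    """
    n = n_hom_ref + n_het + n_hom_alt
    k = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    probs = {}
    for h in range(k % 2, min(k, 2 * n - k) + 1, 2):
        hom_min = (k - h) // 2
        hom_maj = n - h - hom_min
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_maj) * math.factorial(h) * math.factorial(hom_min),
        )
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(17, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 9) == 1.0

    @pytest.mark.parametrize(
        "counts", [(3, 5, 2), (0, 2, 0), (1, 0, 1), (10, 1, 10), (5, 5, 5), (0, 1, 12)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    @settings(deadline=None, max_examples=200)
    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
    )
    def test_symmetric_under_homozygote_swap(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_p(a, b, c) == hwe_exact_p(c, b, a)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.integers(0, 100, size=3)
            if a + b + c == 0:
                continue
            p = hwe_exact_p(int(a), int(b), int(c))
            assert 0 < p <= 1

    def test_extreme_het_excess_is_significant(self):
        # 200 heterozygotes, no homozygotes: far from HW proportions
        assert hwe_exact_p(0, 200, 0) < 1e-6


class TestApplyQC:
    def _clean_cohort(self, n=200, m=30, seed=1):
        """HWE-balanced, fully typed cohort: nothing should be removed."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.5, size=m)
        calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        return build_matrix(calls)

    def test_clean_cohort_untouched(self):
        gm = self._clean_cohort()
        out, report = apply_qc(gm)
        assert out.calls.shape == gm.calls.shape
        assert report.markers_removed_maf == 0
        assert report.samples_removed_call_rate == 0

    def test_low_maf_marker_removed_and_tallied(self):
        gm = self._clean_cohort(n=1000, m=10)
        # force one marker to MAF 0.005: 10 minor alleles in 2000
        gm.calls[:, 4] = 0
        gm.calls[:10, 4] = 1
        out, report = apply_qc(gm)
        assert out.n_markers == 9
        assert report.markers_removed_maf == 1
        assert report.markers_removed_call_rate == 0
        assert "snp4" not in out.markers["snp_id"].tolist()

    def test_sample_call_rate_boundary(self):
        gm = self._clean_cohort(n=20, m=100, seed=5)
        gm.calls[0, :8] = MISSING  # 8% missing: kept (rate 0.92 > 0.9)
        gm.calls[1, :12] = MISSING  # 12% missing: dropped (rate 0.88)
        out, report = apply_qc(
            gm, QCParams(min_snp_call_rate=0.0, min_maf=0.0, min_hwe_p=0.0)
        )
        assert report.samples_removed_call_rate == 1
        assert "S1" not in out.samples and "S0" in out.samples

    def test_marker_call_rate_filter(self):
        gm = self._clean_cohort(n=100, m=100)
        gm.calls[:6, 3] = MISSING  # marker call rate 0.94 < 0.95
        out, report = apply_qc(gm)
        assert report.markers_removed_call_rate == 1
        assert report.samples_removed_call_rate == 0
        assert out.n_markers == 99

    def test_hwe_failure_tallied_last(self):
        gm = self._clean_cohort(n=300, m=5)
        gm.calls[:, 2] = 1  # all heterozygous: extreme HWE departure
        out, report = apply_qc(gm)
        assert report.markers_removed_hwe == 1
        # not double-counted under MAF (MAF is 0.5 here)
        assert report.markers_removed_maf == 0

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        gm = self._clean_cohort(n=150, m=60, seed=2)
        miss = rng.random(gm.calls.shape) < 0.02
        gm.calls[miss] = MISSING
        once, _ = apply_qc(gm)
        twice, report2 = apply_qc(once)
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert report2.n_markers_out == once.n_markers

    def test_empty_cohort_error(self):
        gm = self._clean_cohort(n=10, m=4)
        gm.calls[:] = MISSING
        with pytest.raises(EmptyCohortError):
            apply_qc(gm)
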