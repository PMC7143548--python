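import numpy as np
import pandas as pd
import pytest

from rohscan import GenotypeMatrix, MISSING


def build_matrix(calls, positions=None, chrom=None, samples=None, spacing=50_000,
                 start=1_000_000):
    """Construct a GenotypeMatrix from a 2-D call array.

    ``positions``/``chrom`` default to a single chromosome 1 with uniform
    ``spacing`` between markers.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = start + spacing * np.arange(m)
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=int),
            "snp_id": [f"snp{j}" for j in range(m)],
            "pos_bp": np.asarray(positions, dtype=np.int64),
        }
    )
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


@pytest.fixture
def matrix_factory():
    return build_matrix


def random_matrix(rng, n_samples, n_markers, hom_prob=0.8, missing_prob=0.02,
                  n_chrom=1, spacing_max=120_000):
    """Random genotype fixture with ROH-like homozygous stretches possible."""
    het_prob = max(1.0 - hom_prob - missing_prob, 0.0)
    p = np.array([hom_prob / 2, hom_prob / 2, het_prob, missing_prob])
    calls = rng.choice(
        [0, 2, 1, MISSING], size=(n_samples, n_markers), p=p / p.sum()
    ).astype(np.int8)
    per_chrom = n_markers // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)
    chrom = np.concatenate([chrom, np.full(n_markers - chrom.size, n_chrom)])
    positions = np.empty(n_markers, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom == c)
        positions[idx] = np.cumsum(rng.integers(1, spacing_max, size=idx.size))
    return build_matrix(calls, positions=positions, chrom=chrom)
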