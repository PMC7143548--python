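"""The exact Hardy-Weinberg test and the QC filter chain.

Shows the exact conditional test on hand-sized genotype counts, then runs
the full filter battery (sample call rate > 0.9, marker call rate >= 0.95,
MAF >= 0.01, HWE p > 1e-6) on a cohort with injected defects.
"""

import numpy as np

from rohscan import MISSING, QCParams, SimConfig, apply_qc, hwe_exact_p, simulate_cohort

print("exact HWE p-values (hom_ref, het, hom_alt):")
for counts in [(25, 50, 25), (3, 5, 2), (40, 10, 40), (0, 100, 0)]:
    print(f"  {counts} -> p = {hwe_exact_p(*counts):.3e}")
# (25,50,25) sits exactly at HW proportions -> p = 1; (40,10,40) has a
# strong heterozygote deficit; (0,100,0) is an extreme excess.

sim = simulate_cohort(
    SimConfig(n_samples=120, n_chromosomes=2, markers_per_chromosome=1000, seed=4)
)
gm = sim.genotypes
rng = np.random.default_rng(0)
gm.calls[0, rng.random(gm.n_markers) < 0.15] = MISSING  # one bad sample
gm.calls[:, 10] = 1  # one marker violating HWE hard
gm.calls[:, 20] = 0
gm.calls[1:4, 20] = 1  # rare marker, MAF ~ 0.0126 among QC-passing samples: kept

clean, report = apply_qc(gm, QCParams())
for name, count in report.to_rows():
    print(f"{name}: {count}")
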