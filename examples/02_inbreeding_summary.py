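"""Cohort-level ROH distribution and inbreeding-by-length-category tables.

Reproduces the standard descriptive battery of an ROH survey: counts and
lengths per animal, the share of segments per length bin (1-5, 5-10,
10-20, >20 Mb), per-chromosome coverage, and mean/CV of F_ROH per
category (long ROH mark recent inbreeding, short ROH ancient inbreeding).
"""

from rohscan import (
    AutosomeExtent,
    SimConfig,
    apply_qc,
    compute_froh,
    detect_roh,
    simulate_cohort,
    summarize_distribution,
)

sim = simulate_cohort(
    SimConfig(n_samples=60, n_chromosomes=6, markers_per_chromosome=2000,
              target_f=0.05, generation_depth=6, seed=11)
)
clean, _ = apply_qc(sim.genotypes)
segments = detect_roh(clean)
extent = AutosomeExtent.from_markers(clean.markers)

summary = summarize_distribution(segments, extent, clean.n_samples)
print("totals:")
print(summary.totals.to_string())
print("\nper length bin (percent of segments, mean per-carrier sum):")
print(summary.per_bin.to_string(index=False))
print("\nper chromosome (count, percent covered):")
print(summary.per_chromosome.to_string(index=False))
print("\nF_ROH per category (mean, coefficient of variation %):")
print(summary.froh_cv.to_string(index=False))

report = compute_froh(segments, extent, samples=clean.samples)
top = report.per_sample.sort_values("froh", ascending=False).head(3)
print("\nthree most inbred animals:")
print(top[["n_roh", "l_roh_bp", "froh"]].to_string())
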